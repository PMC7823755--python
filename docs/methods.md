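# Methods

This note records the models the package fits, the conventions and
numerical choices behind them, what the synthetic-herd generator does and
does not emulate, and the known limitations.

## Pedigree algebra

The numerator relationship matrix **A** is built by the tabular method with
full inbreeding accounting: a_ij = ½(a_{j,s(i)} + a_{j,d(i)}) for j
preceding i and a_ii = 1 + ½ a_{s(i),d(i)}; a missing parent contributes
zero.  Its inverse uses Henderson's rules with Mendelian-sampling variances
d_i = ½ − ¼(F_s + F_d) (¾ − ¼F_p with one parent, 1 with none), the
inbreeding coefficients taken from the tabular diagonal, so the two routes
agree to machine precision (tested to 1e−8 at 200 animals, and against a
gene-dropping Monte-Carlo estimate of 2×kinship).  Pedigrees are
canonicalized by Kahn topological sort with ties broken by (birth order,
id), so record input order never affects results; cycles and duplicate ids
are hard errors.

Breed composition is a three-group simplex (Saanen; ANTO = Alpine, Nubian,
Toggenburg, other; unknown) propagated down the pedigree as the parent
average, a missing parent contributing all-"unknown".  General heterosis is
1 − Σ_j d_j² over those fractions: 0 for purebreds, exactly ½ for an F1
between two pure groups, at most 1 − 1/3 with three groups.

## Phenotype edits and SNP quality control

Lactation records are removed when lactation length < 105 d, milk < 100 kg,
fat or protein < 3 kg, or |DMKD| > 90 d.  The removal inequalities are
strict, so boundary records are kept.  Somatic cell score is the mean
log₂(SCC) over herd tests.  Genotype QC removes animals with call rate
< 95% first, then markers with call rate < 90%, MAF < 1%, or a 1-df χ²
Hardy–Weinberg test p < 1e−6 (no continuity correction, pooled across
breeds).  Missing dosages are then mean-imputed per marker and the columns
centered; the centered matrix is the marker-covariate input of the
single-step model.  The QC is idempotent and order-insensitive in the kept
set because all rules are conjunctive.

## Pedigree BLUP

The fixed design holds an intercept, parity-class indicators (classes 1–4
and ≥5; the lowest class present is the reference), and centered DMKD, DIM
and heterosis covariates (centering only shifts the intercept; DIM enters
linearly).  Breed enters as regressions on the ANTO and unknown fractions,
the Saanen coefficient constrained to zero by dropping its column.
Variance components are treated as known inputs per trait (milk
9098.6 + 1011.0 genetic / 30345.0 residual; fat 8.66 + 1.33 / 35.20;
protein 5.69 + 0.88 / 23.10; SCS 0.51 + 0.08 / 2.50 — kg² and log₂² units)
and are never re-estimated.  Solutions come from the mixed-model equations
with λ = σ²e/σ²g on the animal block through **A**⁻¹; PEV is the animal
block of the dense inverse of the coefficient matrix times σ²e — exact, no
approximation, feasible because herd-scale systems stay below a few
thousand equations.  Reliability is 1 − PEV/σ²g and accuracy its square
root; PEV outside [0, σ²g] (possible for inbred animals, whose prior
variance is (1+F)σ²g, or through fixed-effect confounding) is clipped with
a warning.  A rank check on the fixed design raises a named error for
confounded or empty columns instead of silently producing one of many
solutions.

## Single-step BayesC

Partitioning the herd by genotype status, the marker covariates of
non-genotyped animals are imputed as **Mₙ** = **A**ₙg **A**gg⁻¹ **M**g,
computed with a Cholesky solve (never an explicit inverse).  The same
projection applied to the genotyped animals' breed fractions yields
**Jₙ**; **J**g keeps all three breed columns including Saanen.  One exact
consequence worth knowing: because breed fractions are deterministic parent
averages, the pedigree projection reproduces them perfectly wherever all
ancestry is recorded, so **J** is identifiable only through animals with
unrecorded parents — in a herd with complete pedigree **J** is exactly
confounded with the intercept and breed design and the model builder
raises.  This mirrors the covariates' purpose (genotyped vs non-genotyped
*founder* differences) and explains the large individual standard errors of
breed and J coefficients; only their per-breed sums are well identified,
and the reporting layer always presents d̂_f + q̂_f with an SE from the
posterior draws of the sum.

The imputation residual ε for non-genotyped animals has prior covariance
(**A**ₙₙ − **A**ₙg**A**gg⁻¹**A**gₙ)(1 − w)σ²g.  Its precision is the
non-genotyped diagonal block of **A**⁻¹ divided by (1 − w)σ²g — a standard
Schur-complement identity — so the sampler never factorizes the dense
conditional covariance.

Priors: fixed effects (including d and q) flat; marker effects the
two-component mixture with π = 0.98 fixed (never sampled) and a common
variance σ²α across loci; all variances scaled-inverse-χ² with ν = 4 and
scales set so the prior means equal the parametric values.  The common
marker variance is allocated so the expected marker-explained variance
matches the SNP variance component: (1 − π) Σₖ 2pₖ(1 − pₖ) E[σ²α] = σ²snp.
The marker-unlinked fraction w defaults to the per-trait ratio of polygenic
to total genetic variance (0.86–0.90 for the default traits) rather than a
single rounded constant, and is configurable.  The default run mode holds
all variances fixed at their parametric values; a sampling mode draws σ²e,
σ²α and σ²g from their full conditionals for variance-recovery work.

The Gibbs sampler is one numba kernel per chain.  Per iteration it updates
(1) all fixed effects as a single multivariate-normal block draw through a
precomputed Cholesky of F′F — this sidesteps the slow single-site mixing of
the nearly confounded d/q columns; (2) each marker's indicator from the
collapsed conditional (effect integrated out) and then its effect, the
standard BayesC scheme; (3) the polygenic effects u single-site through the
sparse rows of **A**⁻¹, and (4) ε likewise through the **A**⁻¹ block.  The
u and ε sweeps cost little next to the marker sweep, so they are repeated
(4×) within each iteration to cut autocorrelation.  A residual vector over
the training records is maintained exactly throughout.  A master seed
drives the kernel's generator; runs are bit-reproducible for a fixed numba
version.  A non-finite residual variance aborts with the seed and
iteration.

**Breeding values and PEV.**  The per-animal genetic part Mα + ε + u is
maintained incrementally inside the kernel (only markers that change touch
it), and its first two moments are accumulated over *every* post-burn-in
iteration, not just the thinned stored draws — at 10,000 iterations this
cuts the Monte-Carlo noise of the per-animal posterior variance severalfold
at negligible cost.  The GBV point estimate adds the posterior means of the
breed and J regressions (Dd̂ + Jq̂) to the genetic part's posterior mean.
PEV is the posterior variance of the genetic part alone: the flat-prior
breed regressions have no genetic-variance bound, and including their
posterior variance can push "reliability" below zero, whereas the genetic
part is bounded by σ²g by construction — and this matches the pedigree
model, whose PEV (the animal block of the MME inverse) likewise excludes
breed-coefficient uncertainty.  Against an exact dense Gaussian-posterior
oracle (π = 0, fixed variances) the accumulated estimates are unbiased
(mean PEV error below 0.1%) with per-animal noise around 1% of σ²g at
8,000 iterations.

Convergence is monitored with the Geweke diagnostic: z = (mean of first
10% − mean of last 50%) / √(s₁/n₁ + s₂/n₂) with Bartlett-windowed spectral
variances (lag window 2n^{1/3}); a numerically constant chain (a fixed
variance) returns 0 by convention.  Under i.i.d. null chains |z| < 1.96
holds in ~93–95% of replicates; a planted mean step is detected at |z| ≫ 3.

## Validation protocol

The phenotyped herd is ranked by birth order (ties by id); the oldest
⌊0.7n⌋ does train the models and the youngest 30% are validated with
records withheld.  Validation animals get every scenario label whose
condition holds — A: both parents recorded; B: sire recorded with ≥ 5
phenotyped progeny; C: dam recorded with ≥ 1 lactation record; D: neither
parent recorded — labels overlap and are reported independently with their
counts.  A second run masks the parents of the scenario-A animals
(re-sorting the pedigree; their breed fractions become "unknown") and
provides the scenario-D accuracies.  Accuracy summaries are means of
per-animal accuracies, not pooled reliabilities.  EBVs and GBVs are put on
one base by subtracting the training-set mean (the base choice is recorded
in every report), and genomic inflation is the OLS slope of standardized
GBV on standardized EBV over the scenario-A animals, with the Pearson
correlation alongside; the expected slope is 1.  Percent gain is
100·(r_GBV − r_EBV)/r_EBV computed from unrounded accuracies and rounded
to an integer for reporting.

## Synthetic herds

The generator emulates the statistical structure of a seasonal,
Saanen-dominated New Zealand herd: 46 sires and a base population of
mostly unphenotyped dams; 839 does by default arriving in three waves
(25/35/40%), each with exactly one lactation record; 97% of matings use
base dams, so only a few does have a phenotyped dam (scenario C stays
rare, as observed); 2% of sires and 5% of dams go unrecorded, populating
the unknown breed group and scenario D; 46% of does genotyped with a bias
toward recent waves.  Founder allele frequencies diverge between Saanen
and ANTO by the Balding–Nichols construction at Fst = 0.10 from ancestral
frequencies uniform on (0.05, 0.95); founders are Hardy–Weinberg within
breed; descendants get genotypes by Mendelian gene dropping at unlinked
loci, an unrecorded parent transmitting an ancestral-frequency allele.

The trait is built generatively to match the analysis models: parity
effects, DMKD and DIM covariates (uniform on ±90 d and 185–305 d —
conventions chosen to match observed ranges, not estimates), breed-group
means (0 / −150 / −50 kg for milk), a heterosis effect of +30 kg, a sparse
marker architecture — 40 QTL among the genotyped markers, one carrying 30%
of the marker-linked variance (the herd is known to segregate a
large-effect milk QTL), scaled so the realized marker variance equals
(1 − w)σ²g — a pedigree polygenic term drawn N(0, **A**wσ²g) via Cholesky,
and normal residuals.  Somatic cell counts are drawn per test, lognormal
around an animal mean, so the score is computed by the same routine as
real herd tests.  Ground truth (true breeding values and their split,
QTL effects, variance components) is returned for recovery tests.
Realized h² at 2,000 does matches the parametric 0.25 within ±0.04.

What the generator does **not** emulate: linkage and LD decay (loci are
unlinked, so marker–QTL LD arises only from family structure and drift),
selection over generations, genotyping errors, repeated lactations, and
herd-by-season environmental structure.  Passing tests therefore show the
estimators are correct under the assumed model, not that real 50K-chip LD
panels will behave identically.

## Problem sizes in the test suite

Tests run the full algorithms at reduced sizes chosen as the package's
own desk-scale conditions: oracle equivalences at 20–230 animals,
the scenario-D contrast at the default herd scale (800 does, 2,000
markers, 10,000-iteration chains), the 20-replicate accuracy-ordering
experiment at 800 does with 800 markers and 4,000-iteration chains, and
variance-recovery at 300 does × 300 markers over 25 replicates.

## Known limitations

* With the parametric variance split (markers carrying ~10–13% of genetic
  variance) and a single herd of ~560 training records, the marker channel
  contains on the order of n·h²_snp ≈ 14 records of information. An exact
  posterior computation (the π = 0 Gaussian oracle) shows the single-step
  posterior variance for validation animals is then essentially equal to
  the pedigree model's PEV — at this scale the mean PEV-based accuracies of
  the two models are statistically tied, and which is larger is a coin
  flip across replicate herds. The clear, reproducible genomic benefit at
  desk scale is the scenario-D contrast (positive accuracy for genotyped
  animals with no pedigree or phenotype, against exactly zero), not the
  herd-wide mean gain; large mean gains require denser panels, stronger
  marker-linked variance, or larger reference populations than a single
  herd provides.
* The d/q confounding means individual breed and J coefficients can wander
  widely between runs; only their sums are comparable across analyses.
* PEV-based accuracies from MCMC carry Monte-Carlo noise; at short chain
  lengths the square-root transform biases mean accuracy slightly
  downward. The streaming-moment estimator reduces this but does not
  remove it for very short chains.
* Variance components are inputs by design; the sampling mode exists for
  recovery testing, not for production variance estimation.
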