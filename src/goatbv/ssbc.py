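"""Single-step BayesC genomic evaluation.

The observation model jointly fits genotyped (g) and non-genotyped (n)
animals:

    y = Xb + ZDd + ZJq + Z(Mα [+ ε for n]) + Wu + e

Marker covariates of non-genotyped animals are imputed from genotyped
relatives through the pedigree, ``M_n = A_ng A_gg⁻¹ M_g``, with a random
imputation-residual effect ε absorbing the error of that projection,
``ε ~ N(0, (A_nn − A_ng A_gg⁻¹ A_gn)(1 − w) σ_g²)``.  The J covariates are
the breed fractions of the genotyped animals (all three groups, including
Saanen) projected the same way, fitted as fixed regressions to absorb mean
breeding-value differences between genotyped and non-genotyped founders of
each breed group.  Marker effects carry the BayesC mixture prior: zero with
probability π (fixed at 0.98), else normal with a common variance; the
residual polygenic effect u ~ N(0, A w σ_g²) carries the marker-unlinked
fraction w of genetic variance.

Genomic breeding values sum every genetic term,
GBV = Dd̂ + Jq̂ + Mα̂ + ε̂ + û; prediction error variances are the
posterior variances of the random genetic part Mα + ε + u, accumulated
over every post-burn-in iteration of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse

from . import _gibbs
from .config import TraitVariances
from .data_prep import GenotypeSet, LactationRecord
from .pblup import (
    EvaluationResult,
    PblupModel,
    build_design,
    reliability_accuracy,
)
from .pedigree import (
    BreedComposition,
    Pedigree,
    compute_A,
    invert_A,
    partition_A,
)

DEFAULT_NU = 4.0  # scaled-inverse-chi^2 degrees of freedom for all variances


# ---------------------------------------------------------------------------
# Covariate imputation
# ---------------------------------------------------------------------------

def impute_marker_covariates(Mg: np.ndarray, Ang: np.ndarray, Agg: np.ndarray) -> np.ndarray:
    """Pedigree-imputed marker covariates ``M_n = A_ng A_gg⁻¹ M_g``.

    Solved with a Cholesky factor of ``A_gg``; the inverse is never formed.
    """
    try:
        cf = linalg.cho_factor(Agg, check_finite=False)
    except linalg.LinAlgError as err:
        raise ValueError("A_gg is singular; cannot impute covariates") from err
    return Ang @ linalg.cho_solve(cf, np.asarray(Mg, dtype=float), check_finite=False)


def build_J(
    composition: BreedComposition,
    genotyped_ids: list[str],
    nongenotyped_ids: list[str],
    Ang: np.ndarray,
    Agg: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """J covariates: genotyped breed fractions and their pedigree projection.

    ``J_g`` is the breed-fraction matrix of the genotyped animals over all
    three groups (unlike D it keeps the Saanen column); ``J_n`` is the same
    pedigree regression used for the marker covariates applied to ``J_g``.
    """
    Jg = composition.matrix(genotyped_ids)
    if len(nongenotyped_ids) == 0:
        return Jg, np.zeros((0, 3))
    Jn = impute_marker_covariates(Jg, Ang, Agg)
    return Jg, Jn


def per_locus_prior_scale(
    sigma_snp_total: float,
    allele_freqs: np.ndarray,
    pi: float,
    nu: float = DEFAULT_NU,
) -> float:
    """Scale S²_α of the scaled-inverse-χ² prior on the common marker variance.

    Chosen so the expected total marker-explained variance matches the SNP
    variance component: ``(1 − π) Σ_k 2 p_k (1 − p_k) E[σ²_α] =
    sigma_snp_total`` with ``E[σ²_α] = ν S² / (ν − 2)``.
    """
    e_var = expected_locus_variance(sigma_snp_total, allele_freqs, pi)
    return e_var * (nu - 2.0) / nu


def expected_locus_variance(
    sigma_snp_total: float, allele_freqs: np.ndarray, pi: float
) -> float:
    """Expected per-locus effect variance implied by the allocation rule."""
    p = np.asarray(allele_freqs, dtype=float)
    het = float(np.sum(2.0 * p * (1.0 - p)))
    if het <= 0:
        raise ValueError("all markers are monomorphic; cannot allocate SNP variance")
    if pi >= 1.0:
        raise ValueError("pi = 1 leaves no marker with an effect")
    return sigma_snp_total / ((1.0 - pi) * het)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class SsbcModel:
    """Assembled single-step design: partitions, covariates, priors."""

    trait: str
    base: PblupModel                  # y, X, Z, D over the training records
    J_full: np.ndarray                # (N, 3) J rows in pedigree order
    M_full: np.ndarray                # (N, p) marker covariates (imputed for n)
    genotyped: list[str]
    nongenotyped: list[str]
    allele_freqs: np.ndarray
    Ainv: sparse.csr_matrix
    Q: sparse.csr_matrix              # [A^-1]_nn over the non-genotyped
    pi: float
    w: float
    sigma_g2_total: float
    sigma_e2: float
    sigma_a2: float                   # common marker-effect variance (expected)
    S2_a: float
    include_J: bool
    n_fixed: int                      # columns of X (before D and J)

    @property
    def animal_order(self) -> list[str]:
        return self.base.animal_order

    @property
    def n_markers(self) -> int:
        return self.M_full.shape[1]


def build_ssbc_model(
    records: list[LactationRecord],
    pedigree: Pedigree,
    composition: BreedComposition,
    genotypes: GenotypeSet,
    trait: str,
    variances: TraitVariances,
    pi: float = 0.98,
    w: float | None = None,
    include_markers: bool = True,
) -> SsbcModel:
    """Assemble the single-step model for one trait.

    ``genotypes`` must already be quality-controlled; its animals define the
    genotyped partition.  With ``include_markers=False`` the marker and J
    terms are dropped (used for the no-marker limit, where the model must
    collapse to pedigree BLUP with ``w = 1``).
    """
    if w is None:
        w = variances.w
    if not (0.0 < w <= 1.0):
        raise ValueError("w must lie in (0, 1]")
    base = build_design(records, composition, pedigree, trait, variances)
    rel = compute_A(pedigree)
    geno_in_ped = [a for a in genotypes.animal_ids if a in set(pedigree.ids)]
    part = partition_A(rel, set(geno_in_ped))
    g, n_ = part.genotyped, part.nongenotyped

    Ainv = sparse.csr_matrix(invert_A(pedigree))
    idx = {a: i for i, a in enumerate(pedigree.ids)}
    ni = np.array([idx[a] for a in n_], dtype=int)
    Q = sparse.csr_matrix(Ainv[np.ix_(ni, ni)]) if len(n_) else sparse.csr_matrix((0, 0))

    N = pedigree.n
    include_J = include_markers and len(n_) > 0
    if include_markers:
        geno_sub = genotypes.subset(animals=g)
        Mg = geno_sub.centered_covariates()
        freqs = geno_sub.allele_freqs()
        if len(n_):
            Mn = impute_marker_covariates(Mg, part.Ang, part.Agg)
        else:
            Mn = np.zeros((0, Mg.shape[1]))
        M_full = np.zeros((N, Mg.shape[1]))
        for r, a in zip(Mg, g):
            M_full[idx[a]] = r
        for r, a in zip(Mn, n_):
            M_full[idx[a]] = r
        sigma_a2 = expected_locus_variance(variances.snp, freqs, pi)
        S2_a = per_locus_prior_scale(variances.snp, freqs, pi)
    else:
        M_full = np.zeros((N, 0))
        freqs = np.zeros(0)
        sigma_a2 = 0.0
        S2_a = 0.0

    J_full = np.zeros((N, 3))
    if include_J:
        Jg, Jn = build_J(composition, g, n_, part.Ang, part.Agg)
        for r, a in zip(Jg, g):
            J_full[idx[a]] = r
        for r, a in zip(Jn, n_):
            J_full[idx[a]] = r

    return SsbcModel(
        trait=trait,
        base=base,
        J_full=J_full,
        M_full=M_full,
        genotyped=g,
        nongenotyped=n_,
        allele_freqs=freqs,
        Ainv=Ainv,
        Q=Q,
        pi=pi,
        w=w,
        sigma_g2_total=variances.total_genetic,
        sigma_e2=variances.residual,
        sigma_a2=sigma_a2,
        S2_a=S2_a,
        include_J=include_J,
        n_fixed=base.X.shape[1],
    )


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------

@dataclass
class McmcRun:
    """Retained draws of every unknown, plus chain metadata."""

    beta: np.ndarray                  # (nkeep, nf) fixed effects incl. d, q
    alpha: np.ndarray                 # (nkeep, p)
    delta: np.ndarray                 # (nkeep, p) inclusion indicators
    u: np.ndarray                     # (nkeep, N)
    eps: np.ndarray                   # (nkeep, nn)
    sigma_e2: np.ndarray
    sigma_g2: np.ndarray
    sigma_a2: np.ndarray
    gen_mean: np.ndarray              # (N,) posterior mean of Mα + ε + u,
    gen_var: np.ndarray               # and its posterior variance, from
                                      # streaming moments over every
                                      # post-burn-in iteration
    col_names: list[str]
    length: int
    burn_in: int
    thin: int
    seed: int
    d_cols: slice = field(default_factory=lambda: slice(0, 0))
    q_cols: slice = field(default_factory=lambda: slice(0, 0))

    @property
    def n_retained(self) -> int:
        return self.beta.shape[0]

    def inclusion_freq(self) -> np.ndarray:
        return self.delta.mean(axis=0) if self.delta.size else np.zeros(0)

    def d_draws(self) -> np.ndarray:
        return self.beta[:, self.d_cols]

    def q_draws(self) -> np.ndarray:
        return self.beta[:, self.q_cols]


class ChainDivergence(RuntimeError):
    pass


def gibbs_chain(
    model: SsbcModel,
    chain_length: int = 50_000,
    burn_in: int = 1_000,
    thin: int = 10,
    seed: int = 2016,
    fixed_variances: bool = True,
    sample_sigma_g: bool | None = None,
    nu: float = DEFAULT_NU,
    n_inner_sweeps: int = 4,
) -> McmcRun:
    """Run the single-site Gibbs sampler and return the retained draws.

    With ``fixed_variances=True`` every variance stays at its parametric
    value; otherwise σ²_e, the common marker variance, and (if
    ``sample_sigma_g``) the total genetic variance get scaled-inverse-χ²
    updates.  All randomness flows from ``seed``.
    """
    if not burn_in < chain_length:
        raise ValueError("burn_in must be smaller than chain_length")
    base = model.base
    y = base.y
    nr = y.shape[0]
    N = len(base.animal_order)
    p = model.n_markers
    idx = {a: i for i, a in enumerate(base.animal_order)}

    blocks = [base.X, base.D_rec]
    names = list(base.x_names) + ["d_anto", "d_unknown"]
    d_cols = slice(base.X.shape[1], base.X.shape[1] + 2)
    if model.include_J:
        rec_rows = np.array([idx[a] for a in base.record_animals])
        blocks.append(model.J_full[rec_rows])
        q0 = d_cols.stop
        names += ["q_saanen", "q_anto", "q_unknown"]
        q_cols = slice(q0, q0 + 3)
    else:
        q_cols = slice(d_cols.stop, d_cols.stop)
    F = np.column_stack(blocks)
    FtF = F.T @ F
    rank = np.linalg.matrix_rank(F)
    if rank < F.shape[1]:
        zero = [names[j] for j in range(F.shape[1]) if abs(F[:, j]).max() == 0]
        raise ValueError(
            f"fixed-effect block rank {rank} < {F.shape[1]}; "
            f"confounded/empty columns: {zero or 'collinear covariates'}"
        )
    try:
        FtF_chol = linalg.cholesky(FtF, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        raise ValueError(
            "fixed-effect block too ill-conditioned to factor; the breed and "
            "J regressions are nearly confounded in this herd"
        ) from err

    rec_rows_all = np.array([idx[a] for a in base.record_animals])
    MpT = np.ascontiguousarray(model.M_full[rec_rows_all].T) if p else np.zeros((0, nr))
    ck = np.array([MpT[k] @ MpT[k] for k in range(p)]) if p else np.zeros(0)

    rec_of_animal = np.full(N, -1, dtype=np.int64)
    for r, a in enumerate(base.record_animals):
        rec_of_animal[idx[a]] = r
    nong = model.nongenotyped
    rec_of_eps = np.full(len(nong), -1, dtype=np.int64)
    animal_of_eps = np.array([idx[a] for a in nong], dtype=np.int64)
    pheno = {a: r for r, a in enumerate(base.record_animals)}
    for i, a in enumerate(nong):
        if a in pheno:
            rec_of_eps[i] = pheno[a]
    MfT = np.ascontiguousarray(model.M_full.T) if p else np.zeros((0, N))

    nkeep = -(-(chain_length - burn_in) // thin)
    nn = len(nong)
    beta_draws = np.zeros((nkeep, F.shape[1]))
    alpha_draws = np.zeros((nkeep, p))
    delta_draws = np.zeros((nkeep, p), dtype=np.uint8)
    u_draws = np.zeros((nkeep, N))
    eps_draws = np.zeros((nkeep, nn))
    sige_draws = np.zeros(nkeep)
    sigg_draws = np.zeros(nkeep)
    siga_draws = np.zeros(nkeep)
    gen_sum = np.zeros(N)
    gen_sumsq = np.zeros(N)

    if sample_sigma_g is None:
        sample_sigma_g = not fixed_variances
    ainv = model.Ainv
    Q = model.Q
    fail_at = _gibbs.run_chain(
        y.astype(float),
        np.ascontiguousarray(F),
        np.ascontiguousarray(FtF_chol),
        MpT,
        MfT,
        ck,
        rec_of_animal,
        ainv.indptr.astype(np.int64), ainv.indices.astype(np.int64), ainv.data,
        Q.indptr.astype(np.int64), Q.indices.astype(np.int64),
        Q.data if Q.nnz else np.zeros(0),
        rec_of_eps,
        animal_of_eps,
        float(model.pi), float(model.w),
        float(model.sigma_g2_total), float(model.sigma_a2), float(model.sigma_e2),
        nu, float(model.sigma_g2_total) * (nu - 2.0) / nu,
        nu, float(model.S2_a),
        nu, float(model.sigma_e2) * (nu - 2.0) / nu,
        not fixed_variances, not fixed_variances, bool(sample_sigma_g),
        int(n_inner_sweeps),
        int(chain_length), int(burn_in), int(thin), int(seed) % (2**31),
        beta_draws, alpha_draws, delta_draws, u_draws, eps_draws,
        sige_draws, sigg_draws, siga_draws,
        gen_sum, gen_sumsq,
    )
    if fail_at >= 0:
        raise ChainDivergence(
            f"residual variance diverged at iteration {fail_at} (seed {seed})"
        )
    cnt = chain_length - burn_in
    gen_mean = gen_sum / cnt
    gen_var = np.maximum(gen_sumsq / cnt - gen_mean**2, 0.0)
    return McmcRun(
        beta=beta_draws, alpha=alpha_draws, delta=delta_draws,
        u=u_draws, eps=eps_draws,
        sigma_e2=sige_draws, sigma_g2=sigg_draws, sigma_a2=siga_draws,
        gen_mean=gen_mean, gen_var=gen_var,
        col_names=names, length=chain_length, burn_in=burn_in, thin=thin,
        seed=seed, d_cols=d_cols, q_cols=q_cols,
    )


# ---------------------------------------------------------------------------
# Genomic breeding values
# ---------------------------------------------------------------------------

def genetic_part_draws(run: McmcRun, model: SsbcModel) -> np.ndarray:
    """Per-draw random genetic merit ``Mα + ε + u``, (n_retained, N).

    This is the part of the genomic breeding value with a genetic-variance
    prior; its posterior variance is the prediction error variance (it is
    bounded by σ_g², unlike the flat-prior breed regressions).
    """
    G = run.u.copy()
    if model.n_markers:
        G += run.alpha @ model.M_full.T
    if run.eps.shape[1]:
        idx = {a: i for i, a in enumerate(model.base.animal_order)}
        cols = np.array([idx[a] for a in model.nongenotyped])
        G[:, cols] += run.eps
    return G


def gbv_draws(run: McmcRun, model: SsbcModel) -> np.ndarray:
    """Per-draw across-breed genomic breeding values, (n_retained, N).

    Each retained draw sums every genetic term: breed regression Dd, the
    genotyped/non-genotyped correction Jq, marker effects Mα, the imputation
    residual ε (zero for genotyped animals), and the residual polygenic u.
    """
    base = model.base
    G = genetic_part_draws(run, model)
    G += run.d_draws() @ base.D_full.T
    if model.include_J:
        G += run.q_draws() @ model.J_full.T
    return G


def gbv(run: McmcRun, model: SsbcModel) -> EvaluationResult:
    """Posterior summary of the chain as an :class:`EvaluationResult`.

    The point estimate is the posterior mean of the across-breed GBV (breed
    and J regressions plus all random genetic terms).  PEV is the posterior
    variance of the genetic-part draws — the breed-mean regressions carry
    flat priors and no genetic variance, so they contribute their posterior
    means to the ranking but stay out of the reliability, exactly as the
    pedigree model's PEV comes from the animal block of the MME inverse.
    """
    pev = run.gen_var
    d_mean = run.d_draws().mean(axis=0)
    mean = run.gen_mean + model.base.D_full @ d_mean
    if model.include_J:
        mean = mean + model.J_full @ run.q_draws().mean(axis=0)
    rel, acc = reliability_accuracy(pev, model.sigma_g2_total)
    breed = {"saanen": 0.0, "anto": float(d_mean[0]), "unknown": float(d_mean[1])}
    fixed = {
        n: float(v)
        for n, v in zip(run.col_names[: model.n_fixed], run.beta.mean(axis=0))
    }
    return EvaluationResult(
        animal_ids=list(model.animal_order),
        bv=mean,
        a_hat=run.gen_mean,
        pev=pev,
        reliability=rel,
        accuracy=acc,
        fixed_effects=fixed,
        breed_effects=breed,
    )


def genetic_variance_draws(run: McmcRun, model: SsbcModel) -> np.ndarray:
    """Per-draw total genetic variance: w σ_g² plus the realized variance of
    the marker term over genotyped animals."""
    out = model.w * run.sigma_g2.copy()
    if model.n_markers and model.genotyped:
        idx = {a: i for i, a in enumerate(model.animal_order)}
        rows = np.array([idx[a] for a in model.genotyped])
        marker_part = run.alpha @ model.M_full[rows].T
        out = out + marker_part.var(axis=1)
    return out


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------

def _spectral_var0(x: np.ndarray) -> float:
    """Spectral density of ``x`` at frequency zero (Bartlett-windowed
    autocovariance sum), an autocorrelation-consistent variance."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    v = float(xc @ xc) / n
    if v == 0.0 or n < 2:
        return 0.0
    max_lag = min(n - 1, int(np.floor(2.0 * n ** (1.0 / 3.0))))
    s = v
    for lag in range(1, max_lag + 1):
        gamma = float(xc[:-lag] @ xc[lag:]) / n
        s += 2.0 * (1.0 - lag / (max_lag + 1.0)) * gamma
    return max(s, 0.0)


def geweke(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain windows.

    ``z = (mean_first − mean_last) / sqrt(s1/n1 + s2/n2)`` with spectral
    variance estimates; defaults compare the first 10% against the last 50%.
    A chain with zero variance in both windows returns 0 by convention.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValueError("Geweke diagnostic needs a chain of length >= 100")
    # a numerically constant chain (e.g. a fixed variance) is converged
    if np.std(x) <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        return 0.0
    n1 = int(np.floor(first * x.size))
    n2 = int(np.floor(last * x.size))
    a, b = x[:n1], x[x.size - n2:]
    s1, s2 = _spectral_var0(a), _spectral_var0(b)
    denom = s1 / n1 + s2 / n2
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def save_run(run: McmcRun, path) -> None:
    """Persist retained draws and chain metadata to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("beta", "alpha", "delta", "u", "eps",
                     "sigma_e2", "sigma_g2", "sigma_a2", "gen_mean", "gen_var"):
            f.create_dataset(name, data=getattr(run, name))
        f.attrs["col_names"] = [n.encode() for n in run.col_names]
        for k in ("length", "burn_in", "thin", "seed"):
            f.attrs[k] = getattr(run, k)
        f.attrs["d_cols"] = (run.d_cols.start, run.d_cols.stop)
        f.attrs["q_cols"] = (run.q_cols.start, run.q_cols.stop)


def load_run(path) -> McmcRun:
    import h5py

    with h5py.File(path, "r") as f:
        kw = {name: f[name][...] for name in
              ("beta", "alpha", "delta", "u", "eps",
               "sigma_e2", "sigma_g2", "sigma_a2", "gen_mean", "gen_var")}
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f.attrs["col_names"]]
        d0, d1 = (int(v) for v in f.attrs["d_cols"])
        q0, q1 = (int(v) for v in f.attrs["q_cols"])
        return McmcRun(
            col_names=names,
            length=int(f.attrs["length"]),
            burn_in=int(f.attrs["burn_in"]),
            thin=int(f.attrs["thin"]),
            seed=int(f.attrs["seed"]),
            d_cols=slice(d0, d1),
            q_cols=slice(q0, q1),
            **kw,
        )


def mc_standard_error(draws: np.ndarray, n_batches: int = 20):
    """Batch-means Monte Carlo standard error (per column for 2-D input)."""
    x = np.asarray(draws, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n = x.shape[0]
    nb = max(2, min(n_batches, n))
    size = n // nb
    means = np.array([x[i * size:(i + 1) * size].mean(axis=0) for i in range(nb)])
    se = means.std(axis=0, ddof=1) / np.sqrt(nb)
    return float(se[0]) if one_d else se
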