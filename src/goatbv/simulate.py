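"""Synthetic multibreed dairy-goat herds with known ground truth.

The generator emulates the statistical structure the evaluation models
assume: a Saanen-dominated herd with ANTO crossbreds, a multi-generation
pedigree with a modest sire pool and occasional unrecorded parents, founder
allele frequencies diverged between breed groups by a Balding–Nichols
construction at a configured Fst, genotypes by Mendelian gene dropping,
~46% of does genotyped with a bias toward recent generations, and a trait
built from parity, kidding-date and days-in-milk covariates, breed-group
means, heterosis, a sparse set of QTL among the markers (one of large
effect), a pedigree polygenic term, and normal residuals.  Somatic cell
counts are drawn per test, lognormal around an animal mean, so the somatic
cell score is computed exactly as for real herd tests.

Ground truth (true breeding values, marker effects, variance components) is
returned alongside, enabling parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import TraitVariances
from .data_prep import GenotypeSet, LactationRecord, compute_scs
from .pedigree import MISSING, BreedComposition, Pedigree, breed_composition, compute_A, heterosis


@dataclass
class SimulationConfig:
    """Default herd sized to the study population: ~839 phenotyped does,
    46 sires, ~46% genotyped, one lactation record each."""

    n_does: int = 839
    n_sires: int = 46
    n_founder_dams: int = 550
    n_generations: int = 3
    generation_weights: tuple[float, ...] = (0.25, 0.35, 0.40)
    dam_founder_fraction: float = 0.97
    saanen_founder_fraction: float = 0.75
    missing_sire_fraction: float = 0.02
    missing_dam_fraction: float = 0.05
    n_markers: int = 2000
    n_qtl: int = 40
    large_qtl_variance_fraction: float = 0.3
    fst: float = 0.10
    maf_low: float = 0.05
    maf_high: float = 0.95
    genotyping_fraction: float = 0.46
    trait: str = "milk"
    variances: TraitVariances | None = None
    w: float | None = None              # None -> derived from variances
    breed_effects: tuple[float, float, float] = (0.0, -150.0, -50.0)
    heterosis_effect: float = 30.0
    mean: float = 1002.0
    parity_effects: tuple[float, ...] = (-120.0, 0.0, 40.0, 40.0, 20.0)
    parity_probs: tuple[float, ...] = (0.15, 0.45, 0.25, 0.10, 0.05)
    dmkd_range: tuple[float, float] = (-90.0, 90.0)
    dim_range: tuple[float, float] = (185.0, 305.0)
    n_scc_tests: int = 8
    scc_log_sd: float = 0.8
    seed: int = 2016

    def __post_init__(self) -> None:
        if self.variances is None:
            self.variances = TraitVariances.for_trait(self.trait)
        if self.w is None:
            self.w = self.variances.w
        if not np.isclose(sum(self.generation_weights), 1.0):
            raise ValueError("generation weights must sum to 1")
        for fr in (
            self.saanen_founder_fraction,
            self.missing_sire_fraction,
            self.missing_dam_fraction,
            self.genotyping_fraction,
            self.fst,
        ):
            if not (0.0 <= fr <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows that the models must recover."""

    true_bv: dict[str, float]             # genetic deviation per animal
    qtl_markers: list[str]
    qtl_effects: np.ndarray
    breed_effects: tuple[float, float, float]
    heterosis_effect: float
    sigma_g2_total: float
    sigma_e2: float
    w: float
    polygenic: dict[str, float] = field(default_factory=dict)
    marker_bv: dict[str, float] = field(default_factory=dict)
    full_dosages: GenotypeSet | None = None
    genotyped_ids: list[str] = field(default_factory=list)
    doe_generation: dict[str, int] = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Multi-generation herd pedigree with founder breed labels.

    Founders (sires and base dams) are purebred; does arrive in
    ``n_generations`` waves, each doe mated from the sire pool and the dams
    available from earlier waves; a small fraction of parents go unrecorded.
    """
    rng = _rng(config.seed, 0)
    records: list[tuple[str, str, str, int]] = []
    founder_breeds: dict[str, str] = {}
    bo = 0
    sires, dams_pool = [], []
    for i in range(config.n_sires):
        a = f"S{i:04d}"
        records.append((a, MISSING, MISSING, bo)); bo += 1
        founder_breeds[a] = "saanen" if rng.random() < config.saanen_founder_fraction else "anto"
        sires.append(a)
    for i in range(config.n_founder_dams):
        a = f"F{i:04d}"
        records.append((a, MISSING, MISSING, bo)); bo += 1
        founder_breeds[a] = "saanen" if rng.random() < config.saanen_founder_fraction else "anto"
        dams_pool.append(a)

    counts = np.round(np.asarray(config.generation_weights) * config.n_does).astype(int)
    counts[-1] = config.n_does - counts[:-1].sum()
    founder_dams = list(dams_pool)
    doe_dams: list[str] = []
    doe_idx = 0
    for gen, n_gen in enumerate(counts, start=1):
        new_does = []
        for _ in range(n_gen):
            a = f"D{doe_idx:05d}"
            doe_idx += 1
            sire = sires[rng.integers(len(sires))]
            # dams are mostly older, non-phenotyped base females: only a few
            # does have a dam with her own lactation record, as in the herd
            if doe_dams and rng.random() > config.dam_founder_fraction:
                dam = doe_dams[rng.integers(len(doe_dams))]
            else:
                dam = founder_dams[rng.integers(len(founder_dams))]
            if rng.random() < config.missing_sire_fraction:
                sire = MISSING
            if rng.random() < config.missing_dam_fraction:
                dam = MISSING
            records.append((a, sire, dam, bo)); bo += 1
            new_does.append(a)
        doe_dams = doe_dams + new_does
    return Pedigree(records=records, founder_breeds=founder_breeds)


def doe_ids(pedigree: Pedigree) -> list[str]:
    """The phenotyped does (non-founder females) in birth order."""
    return [a for a in pedigree.ids if a.startswith("D")]


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[GenotypeSet, GenotypeSet, list[str]]:
    """Genotypes for every animal plus the observed (genotyped-subset) panel.

    Founder allele frequencies per breed come from the Balding–Nichols
    construction: ancestral frequency p, breed frequency
    ``Beta(p(1−F)/F, (1−p)(1−F)/F)`` at the configured Fst.  Founders are
    Hardy–Weinberg within breed; descendants inherit one allele per parent
    per marker (unlinked loci); an unrecorded parent contributes an allele
    at the ancestral frequency.  Genotyping covers the configured fraction
    of does, weighted toward recent generations.

    Returns (full panel over all animals, observed panel, genotyped ids).
    """
    rng = _rng(config.seed, 1)
    m = config.n_markers
    p_anc = rng.uniform(config.maf_low, config.maf_high, size=m)
    if config.fst > 0:
        c = (1.0 - config.fst) / config.fst
        p_breed = {
            b: rng.beta(p_anc * c, (1.0 - p_anc) * c)
            for b in ("saanen", "anto")
        }
    else:
        p_breed = {"saanen": p_anc, "anto": p_anc}

    idx = {a: i for i, a in enumerate(pedigree.ids)}
    n = pedigree.n
    # haplotypes as two allele arrays per animal
    h1 = np.zeros((n, m), dtype=np.int8)
    h2 = np.zeros((n, m), dtype=np.int8)
    for a, s, d, _bo in pedigree.records:
        i = idx[a]
        if s == MISSING and d == MISSING:
            pb = p_breed.get(pedigree.founder_breeds.get(a), p_anc)
            h1[i] = rng.random(m) < pb
            h2[i] = rng.random(m) < pb
        else:
            for h, parent in ((h1, s), (h2, d)):
                if parent == MISSING:
                    h[i] = rng.random(m) < p_anc
                else:
                    j = idx[parent]
                    pick = rng.random(m) < 0.5
                    h[i] = np.where(pick, h1[j], h2[j])
    dosages = (h1 + h2).astype(float)
    marker_ids = [f"snp{k:05d}" for k in range(m)]
    full = GenotypeSet(animal_ids=list(pedigree.ids), marker_ids=marker_ids,
                       dosages=dosages)

    does = doe_ids(pedigree)
    gens = np.array([_generation_of(a, pedigree) for a in does], dtype=float)
    weights = 1.0 + gens  # later generations more likely genotyped
    weights /= weights.sum()
    n_geno = int(round(config.genotyping_fraction * len(does)))
    chosen = rng.choice(len(does), size=n_geno, replace=False, p=weights)
    genotyped = sorted((does[i] for i in chosen), key=lambda a: idx[a])
    obs = full.subset(animals=genotyped)
    return full, obs, genotyped


def _generation_of(animal: str, pedigree: Pedigree) -> int:
    # does were appended wave by wave; birth order encodes recency
    n_founders = sum(1 for a in pedigree.ids if not a.startswith("D"))
    rank = pedigree.birth_order(animal) - n_founders
    return rank  # monotone proxy; only relative recency matters


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeSet,
    config: SimulationConfig,
) -> tuple[list[LactationRecord], GroundTruth]:
    """Phenotypes for every doe plus the full ground truth.

    ``genotypes`` must be the full (pre-masking) panel so true marker
    breeding values cover non-genotyped animals too.  The trait is

        y = μ + parity + β·DMKD + β·DIM + breed mean + heterosis·h
            + Σ QTL effects + polygenic + residual

    with the polygenic term drawn ``N(0, A w σ_g²)`` through a pedigree
    Cholesky and QTL placed among the markers so that the marker-linked
    variance is (1 − w) σ_g².
    """
    rng = _rng(config.seed, 2)
    var = config.variances
    w = config.w
    sigma_g2 = var.total_genetic
    comp = breed_composition(pedigree)

    # --- QTL effects among markers ---------------------------------------
    m = config.n_markers
    n_qtl = min(config.n_qtl, m)
    X = np.asarray(genotypes.dosages)
    freqs = X.mean(axis=0) / 2.0
    target = (1.0 - w) * sigma_g2
    if n_qtl == 0 or target <= 0:
        qtl_pos = np.zeros(0, dtype=int)
        beta = np.zeros(0)
        marker_bv_vec = np.zeros(X.shape[0])
    else:
        qtl_pos = rng.choice(m, size=n_qtl, replace=False)
        het = 2.0 * freqs[qtl_pos] * (1.0 - freqs[qtl_pos])
        het = np.maximum(het, 1e-6)
        # one large-effect QTL, remainder equal expected contributions
        shares = np.full(
            n_qtl, (1.0 - config.large_qtl_variance_fraction) / max(n_qtl - 1, 1)
        )
        shares[0] = config.large_qtl_variance_fraction if n_qtl > 1 else 1.0
        beta = rng.choice([-1.0, 1.0], size=n_qtl) * np.sqrt(shares * target / het)
        marker_bv_vec = (X[:, qtl_pos] - 2.0 * freqs[qtl_pos]) @ beta

    # --- polygenic term through the pedigree ------------------------------
    A = compute_A(pedigree).A
    L = np.linalg.cholesky(A + 1e-10 * np.eye(A.shape[0]))
    poly_vec = L @ rng.standard_normal(A.shape[0]) * np.sqrt(w * sigma_g2)

    ids = list(pedigree.ids)
    true_bv = {a: float(marker_bv_vec[i] + poly_vec[i]) for i, a in enumerate(ids)}

    # --- records for every doe --------------------------------------------
    d_true = np.asarray(config.breed_effects)
    records: list[LactationRecord] = []
    doe_gen: dict[str, int] = {}
    for a in doe_ids(pedigree):
        parity = int(rng.choice(len(config.parity_probs), p=config.parity_probs)) + 1
        dmkd = float(rng.uniform(*config.dmkd_range))
        dim = float(rng.uniform(*config.dim_range))
        frac = comp.row(a)
        het_cov = heterosis(comp, a)
        genetic = float(frac @ d_true) + true_bv[a]
        mean_y = (
            config.mean
            + config.parity_effects[min(parity, 5) - 1]
            + 0.3 * dmkd
            + 0.5 * (dim - np.mean(config.dim_range))
            + config.heterosis_effect * het_cov
            + genetic
        )
        value = mean_y + float(rng.standard_normal()) * np.sqrt(var.residual)
        scc = rng.lognormal(mean=np.log(300_000.0), sigma=config.scc_log_sd,
                            size=config.n_scc_tests)
        scs = compute_scs(scc)
        records.append(
            LactationRecord(
                animal_id=a,
                milk_yield=value if config.trait == "milk" else 1000.0,
                fat_yield=value if config.trait == "fat" else 30.0,
                protein_yield=value if config.trait == "protein" else 30.0,
                scs=value if config.trait == "scs" else scs,
                lactation_length=float(rng.uniform(200, 305)),
                dim=dim,
                dmkd=dmkd,
                parity=parity,
            )
        )
        doe_gen[a] = _generation_of(a, pedigree)

    truth = GroundTruth(
        true_bv=true_bv,
        qtl_markers=[genotypes.marker_ids[k] for k in qtl_pos],
        qtl_effects=beta,
        breed_effects=config.breed_effects,
        heterosis_effect=config.heterosis_effect,
        sigma_g2_total=sigma_g2,
        sigma_e2=var.residual,
        w=w,
        polygenic={a: float(poly_vec[i]) for i, a in enumerate(ids)},
        marker_bv={a: float(marker_bv_vec[i]) for i, a in enumerate(ids)},
        full_dosages=genotypes,
        doe_generation=doe_gen,
    )
    return records, truth


@dataclass
class SyntheticHerd:
    """One complete simulated dataset."""

    pedigree: Pedigree
    composition: BreedComposition
    genotypes: GenotypeSet          # observed, genotyped subset
    genotyped_ids: list[str]
    records: list[LactationRecord]
    truth: GroundTruth
    config: SimulationConfig


def simulate_herd(config: SimulationConfig | None = None, **overrides) -> SyntheticHerd:
    """Generate a full herd: pedigree, genotypes, phenotypes, truth."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    ped = simulate_pedigree(config)
    full, obs, genotyped = simulate_genotypes(ped, config)
    records, truth = simulate_phenotypes(ped, full, config)
    truth.genotyped_ids = genotyped
    return SyntheticHerd(
        pedigree=ped,
        composition=breed_composition(ped),
        genotypes=obs,
        genotyped_ids=genotyped,
        records=records,
        truth=truth,
        config=config,
    )


def realized_h2(records: list[LactationRecord], truth: GroundTruth, trait: str) -> float:
    """Realized narrow-sense heritability: Var(true BV)/Var(BV + residual
    deviation) over the phenotyped does, covariate effects removed by truth."""
    bv = np.array([truth.true_bv[r.animal_id] for r in records])
    # phenotype minus everything but genetics and residual is bv + e; use
    # the identity Var(y_adj) = Var(bv) + sigma_e2 instead of refitting
    return float(np.var(bv) / (np.var(bv) + truth.sigma_e2))
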