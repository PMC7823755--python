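"""Pedigree-based BLUP: the single-trait multibreed animal model.

The model is ``y = Xb + ZDd + Za + e`` with fixed effects b (parity
contemporary group, deviation from median kidding date, days in milk,
general heterosis), breed-fraction regressions d for the ANTO and unknown
groups (the Saanen coefficient is constrained to zero), and additive animal
effects ``a ~ N(0, A σ_g²)`` over every pedigree animal.  Across-breed
breeding values are ``EBV = Dd̂ + â``.  Solutions come from Henderson's
mixed model equations; prediction error variances from the dense inverse of
the MME coefficient matrix, giving reliability ``1 − PEV/σ_g²`` and accuracy
its square root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import linalg

from .config import TraitVariances
from .data_prep import LactationRecord
from .pedigree import BreedComposition, Pedigree, heterosis


@dataclass
class PblupModel:
    """Design matrices and variance components for one trait."""

    trait: str
    y: np.ndarray                    # (n_records,)
    X: np.ndarray                    # fixed effects incl. intercept
    x_names: list[str]
    D_rec: np.ndarray                # breed design on records (ANTO, unknown)
    D_full: np.ndarray               # breed design over all pedigree animals
    Z: np.ndarray                    # record → animal incidence
    animal_order: list[str]
    record_animals: list[str]
    sigma_g2: float
    sigma_e2: float


@dataclass
class EvaluationResult:
    """Per-animal breeding values with their precision measures."""

    animal_ids: list[str]
    bv: np.ndarray                  # EBV (or GBV) per animal, trait units
    a_hat: np.ndarray               # additive (or summed genetic) solutions
    pev: np.ndarray
    reliability: np.ndarray
    accuracy: np.ndarray
    fixed_effects: dict[str, float] = field(default_factory=dict)
    breed_effects: dict[str, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal_ids,
                "bv": self.bv,
                "a_hat": self.a_hat,
                "pev": self.pev,
                "reliability": self.reliability,
                "accuracy": self.accuracy,
            }
        )


def build_design(
    records: list[LactationRecord],
    composition: BreedComposition,
    pedigree: Pedigree,
    trait: str,
    variances: TraitVariances,
) -> PblupModel:
    """Assemble y, X, D and Z for one trait.

    X holds an intercept, parity-class indicators with class 1 as the
    reference, and centered DMKD, DIM, and heterosis covariates (centering
    only shifts the intercept; breeding values are unaffected).  D carries
    the ANTO and unknown breed fractions; the Saanen column is dropped,
    implementing the zero constraint on the Saanen coefficient.
    """
    missing = [r.animal_id for r in records if r.animal_id not in composition.fractions]
    if missing:
        raise ValueError(f"phenotyped animals absent from pedigree: {missing[:5]}")
    seen = set()
    for r in records:
        if r.animal_id in seen:
            raise ValueError(f"more than one lactation record for {r.animal_id}")
        seen.add(r.animal_id)

    n = len(records)
    y = np.array([r.trait(trait) for r in records])

    parity_classes = sorted({r.parity_class for r in records})
    cols = [np.ones(n)]
    names = ["intercept"]
    for pc in parity_classes[1:]:  # class 1 (lowest present) is the reference
        cols.append(np.array([1.0 if r.parity_class == pc else 0.0 for r in records]))
        names.append(f"parity_{pc}" if pc < 5 else "parity_5plus")
    for cov, nm in (
        (np.array([r.dmkd for r in records]), "dmkd"),
        (np.array([r.dim for r in records]), "dim"),
        (np.array([heterosis(composition, r.animal_id) for r in records]), "heterosis"),
    ):
        cols.append(cov - cov.mean())
        names.append(nm)
    X = np.column_stack(cols)

    animal_order = list(pedigree.ids)
    idx = {a: i for i, a in enumerate(animal_order)}
    Z = np.zeros((n, len(animal_order)))
    for i, r in enumerate(records):
        Z[i, idx[r.animal_id]] = 1.0
    D_full = composition.matrix(animal_order)[:, 1:]  # (ANTO, unknown)
    D_rec = np.array([composition.row(r.animal_id)[1:] for r in records])

    return PblupModel(
        trait=trait,
        y=y,
        X=X,
        x_names=names,
        D_rec=D_rec,
        D_full=D_full,
        Z=Z,
        animal_order=animal_order,
        record_animals=[r.animal_id for r in records],
        sigma_g2=variances.total_genetic,
        sigma_e2=variances.residual,
    )


def solve_mme(model: PblupModel, Ainv: np.ndarray) -> EvaluationResult:
    """Solve Henderson's mixed model equations and extract PEV.

    The coefficient matrix stacks the fixed block [X | ZD] against the
    animal block ``Z'Z + λ A⁻¹`` with ``λ = σ_e²/σ_g²``; its dense inverse
    yields the animal-block prediction error variances ``C^aa σ_e²``.
    """
    if model.sigma_g2 <= 0 or model.sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    nd = model.D_rec.shape[1]
    F = np.column_stack([model.X, model.D_rec]) if nd else model.X
    f_names = model.x_names + ["breed_anto", "breed_unknown"][:nd]
    rank = np.linalg.matrix_rank(F)
    if rank < F.shape[1]:
        sv = np.linalg.svd(F, compute_uv=False)
        suspect = [f_names[j] for j in range(F.shape[1]) if F[:, j].std() == 0]
        raise ValueError(
            "singular fixed-effect block (rank "
            f"{rank} < {F.shape[1]}); confounded or constant columns: "
            f"{suspect or 'collinear covariates'}; singular values tail {sv[-3:]}"
        )
    Z = model.Z
    lam = model.sigma_e2 / model.sigma_g2
    nf, na = F.shape[1], Z.shape[1]
    C = np.empty((nf + na, nf + na))
    C[:nf, :nf] = F.T @ F
    C[:nf, nf:] = F.T @ Z
    C[nf:, :nf] = C[:nf, nf:].T
    C[nf:, nf:] = Z.T @ Z + lam * Ainv
    rhs = np.concatenate([F.T @ model.y, Z.T @ model.y])
    Cinv = linalg.inv(C, check_finite=False)
    sol = Cinv @ rhs
    beta, a_hat = sol[:nf], sol[nf:]
    pev = np.diag(Cinv)[nf:] * model.sigma_e2
    rel, acc = reliability_accuracy(pev, model.sigma_g2)
    d_arr = beta[len(model.x_names):]
    d_hat = (
        {"saanen": 0.0, "anto": float(d_arr[0]), "unknown": float(d_arr[1])}
        if nd == 2 else {}
    )
    bv = ebv_from_solutions(a_hat, model.D_full, d_arr)
    return EvaluationResult(
        animal_ids=list(model.animal_order),
        bv=bv,
        a_hat=a_hat,
        pev=pev,
        reliability=rel,
        accuracy=acc,
        fixed_effects=dict(zip(model.x_names, beta[: len(model.x_names)])),
        breed_effects=d_hat,
    )


def ebv_from_solutions(a_hat: np.ndarray, D_full: np.ndarray, d_hat: np.ndarray) -> np.ndarray:
    """Across-breed breeding values ``EBV_i = D_i d̂ + â_i`` for every animal."""
    return D_full @ d_hat + a_hat


def reliability_accuracy(pev: np.ndarray, sigma_g2: float) -> tuple[np.ndarray, np.ndarray]:
    """Reliability ``1 − PEV/σ_g²`` and accuracy ``√reliability``.

    PEV outside [0, σ_g²] (possible through numerical round-off or posterior
    variance of fixed-effect contrasts) is clipped with a warning.
    """
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    pev = np.atleast_1d(np.asarray(pev, dtype=float))
    if np.any(pev < -1e-6 * sigma_g2) or np.any(pev > sigma_g2 * (1 + 1e-6)):
        warnings.warn("PEV outside [0, sigma_g2]; clipping", RuntimeWarning)
    rel = np.clip(1.0 - pev / sigma_g2, 0.0, 1.0)
    return rel, np.sqrt(rel)


def write_solutions_tsv(result: EvaluationResult, trait: str, path) -> None:
    """Per-animal solutions TSV: animal, trait, EBV, PEV, reliability, accuracy."""
    df = result.frame()
    df.insert(1, "trait", trait)
    df.to_csv(path, sep="\t", index=False)
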