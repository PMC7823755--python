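"""Validation protocol and accuracy/inflation diagnostics.

The herd is split by age: the oldest 70% of phenotyped does train the
models, the youngest 30% are validated with their phenotypes withheld.
Validation animals are classified by available pedigree information:
(A) both parents recorded, (B) sire recorded with ≥ 5 progeny in the herd,
(C) dam recorded with ≥ 1 lactation record, (D) neither parent recorded.
Labels may overlap and are reported independently.  A second run masks the
parents of the scenario-A animals to measure prediction with no pedigree
links.  Breeding values from the two models are put on one base by
subtracting the training-set mean, and the OLS slope of standardized GBV on
standardized EBV measures genomic inflation (expected value 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import MISSING, Pedigree


@dataclass
class ValidationDesign:
    """Age-based training/validation split with scenario labels."""

    training_ids: list[str]
    validation_ids: list[str]
    scenario_labels: dict[str, set[str]] = field(default_factory=dict)
    masked_pedigree: Pedigree | None = None


def age_split(
    herd: list[tuple[str, int]], fraction_training: float = 0.7
) -> ValidationDesign:
    """Split (animal, birth_order) pairs: oldest ``floor(f·n)`` to training.

    Ties in birth order break by id, oldest = smallest birth order.
    """
    if not (0.0 < fraction_training < 1.0):
        raise ValueError("training fraction must lie in (0, 1)")
    if len(herd) < 2:
        raise ValueError("need at least two animals to split")
    ranked = sorted(herd, key=lambda t: (t[1], t[0]))
    n_train = int(np.floor(fraction_training * len(herd)))
    return ValidationDesign(
        training_ids=[a for a, _bo in ranked[:n_train]],
        validation_ids=[a for a, _bo in ranked[n_train:]],
    )


def classify_scenarios(
    design: ValidationDesign,
    pedigree: Pedigree,
    phenotyped: set[str],
    min_progeny: int = 5,
    min_dam_lactations: int = 1,
) -> dict[str, set[str]]:
    """Assign each validation animal every scenario label whose condition
    holds (A/B overlap as in the study herd); returns and stores the map."""
    progeny = pedigree.progeny_counts(within=phenotyped)
    labels: dict[str, set[str]] = {}
    for a in design.validation_ids:
        sire, dam = pedigree.parents(a)
        lab = set()
        if sire != MISSING and dam != MISSING:
            lab.add("A")
        if sire != MISSING and progeny.get(sire, 0) >= min_progeny:
            lab.add("B")
        if dam != MISSING and (dam in phenotyped) >= min_dam_lactations:
            lab.add("C")
        if sire == MISSING and dam == MISSING:
            lab.add("D")
        labels[a] = lab
    design.scenario_labels = labels
    return labels


def mask_parents(pedigree: Pedigree, target_ids: set[str]) -> Pedigree:
    """Return a pedigree with the sire and dam of every target removed."""
    records = [
        (a, MISSING, MISSING, bo) if a in target_ids else (a, s, d, bo)
        for a, s, d, bo in pedigree.records
    ]
    founder_breeds = dict(pedigree.founder_breeds)
    return Pedigree(records=records, founder_breeds=founder_breeds)


def standardize_to_base(
    values: np.ndarray, ids: list[str], base_ids: set[str]
) -> np.ndarray:
    """Subtract the mean over ``base_ids`` so the base averages exactly zero."""
    base_idx = [i for i, a in enumerate(ids) if a in base_ids]
    if not base_idx:
        raise ValueError("empty base group for standardization")
    v = np.asarray(values, dtype=float)
    return v - v[base_idx].mean()


def inflation_slope(gbv_std: np.ndarray, ebv_std: np.ndarray) -> tuple[float, float]:
    """OLS slope of GBV on EBV and their Pearson correlation.

    A slope below 1 indicates deflated genomic predictions (or inflated
    pedigree ones); the expected value under agreement is 1.
    """
    g = np.asarray(gbv_std, dtype=float)
    e = np.asarray(ebv_std, dtype=float)
    if g.size != e.size or g.size < 3:
        raise ValueError("need at least three paired values")
    if np.var(e) == 0:
        raise ValueError("zero EBV variance; slope undefined")
    res = stats.linregress(e, g)
    return float(res.slope), float(res.rvalue)


def combine_breed_and_J(
    d_hat: dict[str, float],
    q_hat: dict[str, float],
    d_draws: np.ndarray | None = None,
    q_draws: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Combined per-breed effect ``d̂_f + q̂_f`` (Saanen's d̂ ≡ 0) with SEs.

    The breed (d) and J (q) regressions are confounded in the single-step
    model; their per-breed sum is the well-identified quantity reported.
    When per-draw solutions are supplied the SE is the posterior standard
    deviation of the per-draw sums; otherwise SEs are returned as NaN.
    """
    if set(d_hat) - set(q_hat):
        raise ValueError(
            f"breed groups differ: d has {sorted(d_hat)}, q has {sorted(q_hat)}"
        )
    out: dict[str, tuple[float, float]] = {}
    order = [b for b in ("saanen", "anto", "unknown") if b in q_hat] or sorted(q_hat)
    for i, breed in enumerate(order):
        total = d_hat.get(breed, 0.0) + q_hat[breed]
        if d_draws is not None and q_draws is not None:
            di = 0.0 if breed == "saanen" else d_draws[:, ["anto", "unknown"].index(breed)]
            se = float(np.std(di + q_draws[:, i], ddof=1))
        else:
            se = float("nan")
        out[breed] = (float(total), se)
    return out


def percent_gain(r_ebv: float, r_gbv: float) -> int:
    """Relative accuracy gain ``100·(r_GBV − r_EBV)/r_EBV`` rounded to an
    integer percent, computed from unrounded accuracies."""
    if r_ebv <= 0:
        raise ValueError("percent gain undefined for zero baseline accuracy")
    return int(round(100.0 * (r_gbv - r_ebv) / r_ebv))


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Per-trait accuracy comparison between the two models."""

    trait: str
    n_validation: int
    mean_ebv_accuracy: float
    mean_gbv_accuracy: float
    gain_percent: int | None
    slope: float
    correlation: float
    scenario_accuracies: dict[str, dict[str, float]]  # label -> model -> mean r
    scenario_counts: dict[str, int]
    combined_breed_effects: dict[str, tuple[float, float]]
    base: str = "training set"

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "n_validation": self.n_validation,
            "mean_ebv_accuracy": self.mean_ebv_accuracy,
            "mean_gbv_accuracy": self.mean_gbv_accuracy,
            "gain_percent": self.gain_percent,
            "inflation_slope": self.slope,
            "correlation": self.correlation,
            "scenario_accuracies": self.scenario_accuracies,
            "scenario_counts": self.scenario_counts,
            "combined_breed_effects": {
                b: {"estimate": v, "se": se}
                for b, (v, se) in self.combined_breed_effects.items()
            },
            "standardization_base": self.base,
        }

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "trait": self.trait,
                "scenario": lab,
                "n": self.scenario_counts.get(lab, 0),
                "ebv_accuracy": acc.get("ebv", float("nan")),
                "gbv_accuracy": acc.get("gbv", float("nan")),
            }
            for lab, acc in sorted(self.scenario_accuracies.items())
        ]
        rows.append(
            {
                "trait": self.trait,
                "scenario": "all",
                "n": self.n_validation,
                "ebv_accuracy": self.mean_ebv_accuracy,
                "gbv_accuracy": self.mean_gbv_accuracy,
            }
        )
        return pd.DataFrame(rows)
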