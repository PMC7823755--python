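"""Phenotype editing and SNP quality control.

Lactation records are edited with the herd-test rules used for the study
herd: lactations shorter than 105 days, milk yield below 100 kg, fat or
protein yield below 3 kg, or a kidding date more than 90 days from the herd
median are removed (boundaries themselves are kept — the rules are strict
inequalities).  Somatic cell score is the mean log2 somatic cell count over
the herd tests.  SNP QC removes animals with call rate < 95%, then markers
with call rate < 90%, minor-allele frequency < 1%, or Hardy–Weinberg
equilibrium test p < 1e−6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ("milk", "fat", "protein", "scs")


@dataclass
class LactationRecord:
    """One 305-day lactation record with its model covariates.

    parity is capped into the contemporary-group classes {1, 2, 3, 4, 5+}
    (class 5 means "fifth or later").
    """

    animal_id: str
    milk_yield: float
    fat_yield: float
    protein_yield: float
    scs: float
    lactation_length: float
    dim: float
    dmkd: float
    parity: int

    @property
    def parity_class(self) -> int:
        return min(int(self.parity), 5)

    def trait(self, name: str) -> float:
        return {
            "milk": self.milk_yield,
            "fat": self.fat_yield,
            "protein": self.protein_yield,
            "scs": self.scs,
        }[name]


def filter_lactations(
    records: list[LactationRecord],
) -> tuple[list[LactationRecord], list[tuple[LactationRecord, str]]]:
    """Apply the lactation edits; dropped records carry the first rule violated.

    Rules (conjunctive, order only affects the reported reason):
    lactation_length ≥ 105 d, milk ≥ 100 kg, fat ≥ 3 kg, protein ≥ 3 kg,
    |DMKD| ≤ 90 d.
    """
    kept, dropped = [], []
    for r in records:
        if r.lactation_length < 105:
            dropped.append((r, "lactation_length<105"))
        elif r.milk_yield < 100:
            dropped.append((r, "milk_yield<100"))
        elif r.fat_yield < 3:
            dropped.append((r, "fat_yield<3"))
        elif r.protein_yield < 3:
            dropped.append((r, "protein_yield<3"))
        elif abs(r.dmkd) > 90:
            dropped.append((r, "|dmkd|>90"))
        else:
            kept.append(r)
    return kept, dropped


def compute_scs(scc_tests) -> float:
    """Somatic cell score: mean of log2(somatic cell count) over herd tests."""
    counts = np.asarray(scc_tests, dtype=float)
    if counts.size == 0:
        raise ValueError("no somatic cell count tests supplied")
    if np.any(counts <= 0):
        raise ValueError("somatic cell counts must be positive")
    return float(np.mean(np.log2(counts)))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSet:
    """Additive-dosage genotypes: animals × markers, NaN for a missing call."""

    animal_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # float, entries in {0,1,2} or NaN
    qc_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def allele_freqs(self) -> np.ndarray:
        """Frequency of the counted allele per marker over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def animal_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def marker_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-marker mean."""
        X = self.dosages.copy()
        mu = np.nanmean(X, axis=0)
        nan = np.isnan(X)
        X[nan] = np.take(mu, np.nonzero(nan)[1])
        return X

    def centered_covariates(self) -> np.ndarray:
        """Mean-imputed dosages with per-marker means subtracted.

        Columns have mean zero over these animals; this is the marker
        covariate matrix the single-step model consumes.
        """
        X = self.mean_imputed()
        return X - X.mean(axis=0)

    def subset(self, animals=None, markers=None) -> "GenotypeSet":
        ai = (
            np.arange(self.n_animals)
            if animals is None
            else np.asarray([self.animal_ids.index(a) for a in animals])
        )
        mi = (
            np.arange(self.n_markers)
            if markers is None
            else np.asarray([self.marker_ids.index(m) for m in markers])
        )
        return GenotypeSet(
            animal_ids=[self.animal_ids[i] for i in ai],
            marker_ids=[self.marker_ids[j] for j in mi],
            dosages=self.dosages[np.ix_(ai, mi)],
            qc_log=list(self.qc_log),
        )


def hwe_test(counts) -> float:
    """1-df χ² goodness-of-fit p-value against Hardy–Weinberg proportions.

    ``counts`` is (n_AA, n_AB, n_BB) where B is the counted allele.  A
    monomorphic marker fits exactly (p = 1).
    """
    n_aa, n_ab, n_bb = (float(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotype observations")
    p = (2 * n_bb + n_ab) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.array([n_aa, n_ab, n_bb])
    mask = exp > 0
    chi2 = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
    return float(stats.chi2.sf(chi2, df=1))


def _marker_hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    n_bb = np.nansum(dosages == 2, axis=0)
    n_ab = np.nansum(dosages == 1, axis=0)
    n_aa = np.nansum(dosages == 0, axis=0)
    n = n_aa + n_ab + n_bb
    p = np.where(n > 0, (2 * n_bb + n_ab) / np.maximum(2 * n, 1), 0.0)
    q = 1.0 - p
    exp = np.stack([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.stack([n_aa, n_ab, n_bb])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    chi2 = terms.sum(axis=0)
    return stats.chi2.sf(chi2, df=1)


def snp_qc(
    genotypes: GenotypeSet,
    animal_call_min: float = 0.95,
    snp_call_min: float = 0.90,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> GenotypeSet:
    """Animal-level then marker-level quality control.

    Animals with call rate below ``animal_call_min`` are removed first; then
    markers failing call rate, minor-allele frequency, or the Hardy–Weinberg
    χ² test (p < ``hwe_alpha``) are removed.  Drop reasons accumulate in
    ``qc_log``.
    """
    for t in (animal_call_min, snp_call_min, maf_min, hwe_alpha):
        if not (0 < t < 1):
            raise ValueError("QC thresholds must lie in (0, 1)")
    log = list(genotypes.qc_log)

    acr = genotypes.animal_call_rates()
    keep_a = acr >= animal_call_min
    for i in np.nonzero(~keep_a)[0]:
        log.append({"kind": "animal", "id": genotypes.animal_ids[i],
                    "reason": f"call_rate<{animal_call_min}", "value": float(acr[i])})
    dos = genotypes.dosages[keep_a]
    animals = [a for a, k in zip(genotypes.animal_ids, keep_a) if k]

    mcr = 1.0 - np.isnan(dos).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = _marker_hwe_pvalues(dos)

    keep_m = np.ones(genotypes.n_markers, dtype=bool)
    for j in range(genotypes.n_markers):
        if mcr[j] < snp_call_min:
            reason, val = f"call_rate<{snp_call_min}", float(mcr[j])
        elif maf[j] < maf_min:
            reason, val = f"maf<{maf_min}", float(maf[j])
        elif hwe_p[j] < hwe_alpha:
            reason, val = f"hwe_p<{hwe_alpha}", float(hwe_p[j])
        else:
            continue
        keep_m[j] = False
        log.append({"kind": "marker", "id": genotypes.marker_ids[j],
                    "reason": reason, "value": val})
    if not keep_m.any():
        raise ValueError("SNP QC removed every marker")
    return GenotypeSet(
        animal_ids=animals,
        marker_ids=[m for m, k in zip(genotypes.marker_ids, keep_m) if k],
        dosages=dos[:, keep_m],
        qc_log=log,
    )


def qc_report(genotypes: GenotypeSet) -> pd.DataFrame:
    """QC drop log as a DataFrame (kind, id, reason, value)."""
    return pd.DataFrame(genotypes.qc_log, columns=["kind", "id", "reason", "value"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_dosage_csv(path) -> GenotypeSet:
    """Headered additive-dosage CSV: first column animal id, one column per
    marker; empty cells are missing calls."""
    df = pd.read_csv(path, index_col=0)
    return GenotypeSet(
        animal_ids=[str(a) for a in df.index],
        marker_ids=[str(m) for m in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def write_dosage_csv(genotypes: GenotypeSet, path) -> None:
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.animal_ids, columns=genotypes.marker_ids
    )
    df.to_csv(path, index_label="animal")


def read_plink(ped_path, map_path) -> GenotypeSet:
    """Read a PLINK text .ped/.map pair into additive dosages.

    Dosage counts the 'B' allele; '0 0' denotes a missing call.
    """
    marker_ids = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                marker_ids.append(parts[1])
    animal_ids, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            animal_ids.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(marker_ids):
                raise ValueError(
                    f".ped row for {parts[1]} has {len(alleles)} alleles, "
                    f"expected {2 * len(marker_ids)}"
                )
            row = np.empty(len(marker_ids))
            for j in range(len(marker_ids)):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    row[j] = np.nan
                else:
                    row[j] = (a1 == "B") + (a2 == "B")
            rows.append(row)
    return GenotypeSet(animal_ids=animal_ids, marker_ids=marker_ids,
                       dosages=np.array(rows))


def write_plink(genotypes: GenotypeSet, ped_path, map_path) -> None:
    """Write a PLINK text .ped/.map pair (alleles A/B, chromosome 1)."""
    with open(map_path, "w") as fh:
        for j, m in enumerate(genotypes.marker_ids):
            fh.write(f"1\t{m}\t0\t{j + 1}\n")
    geno_strings = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(ped_path, "w") as fh:
        for i, a in enumerate(genotypes.animal_ids):
            fields = ["HERD", a, "0", "0", "0", "-9"]
            for x in genotypes.dosages[i]:
                fields.append("0 0" if np.isnan(x) else geno_strings[float(x)])
            fh.write(" ".join(fields) + "\n")


def read_phenotype_csv(path) -> list[LactationRecord]:
    """Phenotype CSV with columns animal,milk,fat,protein,scs,
    lactation_length,dim,dmkd,parity."""
    df = pd.read_csv(path)
    return [
        LactationRecord(
            animal_id=str(r.animal),
            milk_yield=float(r.milk),
            fat_yield=float(r.fat),
            protein_yield=float(r.protein),
            scs=float(r.scs),
            lactation_length=float(r.lactation_length),
            dim=float(r.dim),
            dmkd=float(r.dmkd),
            parity=int(r.parity),
        )
        for r in df.itertuples()
    ]


def write_phenotype_csv(records: list[LactationRecord], path) -> None:
    pd.DataFrame(
        {
            "animal": [r.animal_id for r in records],
            "milk": [r.milk_yield for r in records],
            "fat": [r.fat_yield for r in records],
            "protein": [r.protein_yield for r in records],
            "scs": [r.scs for r in records],
            "lactation_length": [r.lactation_length for r in records],
            "dim": [r.dim for r in records],
            "dmkd": [r.dmkd for r in records],
            "parity": [r.parity for r in records],
        }
    ).to_csv(path, index=False)
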