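"""Pedigree algebra shared by both evaluation models.

The numerator relationship matrix **A** holds the expected additive genetic
relationships implied by the pedigree (twice the kinship coefficients), with
diagonal ``1 + F_i`` where ``F_i`` is the inbreeding coefficient.  Both the
pedigree BLUP animal model and the single-step Bayesian regression consume
**A** (or its inverse / genotyped–non-genotyped partitions), so everything
pedigree-shaped lives here: topological sorting, the tabular method for
**A**, Henderson's rules for ``A⁻¹`` with inbreeding, breed-composition
recursion, and the general heterosis covariate.

Animal identifiers are opaque strings; numeric recoding is internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

MISSING = ""

#: Breed-group order used everywhere: Saanen, ANTO (Alpine/Nubian/Toggenburg/
#: other aggregate), and "unknown" (unrecorded ancestry).
BREED_GROUPS = ("saanen", "anto", "unknown")


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, duplicates)."""


@dataclass
class Pedigree:
    """An ordered pedigree: each record is (animal, sire, dam, birth_order).

    ``founder_breeds`` maps founder ids to a breed-group label in
    :data:`BREED_GROUPS`; founders without a label are treated as unknown
    breed.  After construction the records are topologically sorted so every
    parent precedes its offspring, with ties broken by (birth_order, id).
    """

    records: list[tuple[str, str, str, int]]
    founder_breeds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            dup = dup[dup > 1].index.tolist()
            raise PedigreeError(f"duplicate animal ids: {dup[:5]}")
        self.records = _toposort(self.records)
        self._index = {r[0]: i for i, r in enumerate(self.records)}
        bad = set(self.founder_breeds) - {b for b in self.founder_breeds
                                          if self.founder_breeds[b] in BREED_GROUPS}
        if bad:
            raise PedigreeError(f"unknown breed labels for: {sorted(bad)[:5]}")

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def index_of(self, animal: str) -> int:
        return self._index[animal]

    def parents(self, animal: str) -> tuple[str, str]:
        r = self.records[self._index[animal]]
        return r[1], r[2]

    def birth_order(self, animal: str) -> int:
        return self.records[self._index[animal]][3]

    def parent_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam index arrays in sorted order, -1 for a missing parent."""
        sire = np.full(self.n, -1, dtype=np.int64)
        dam = np.full(self.n, -1, dtype=np.int64)
        for i, (_a, s, d, _bo) in enumerate(self.records):
            if s != MISSING:
                sire[i] = self._index[s]
            if d != MISSING:
                dam[i] = self._index[d]
        return sire, dam

    def progeny_counts(self, within: set[str] | None = None) -> dict[str, int]:
        """Number of recorded offspring per animal, optionally counting only
        offspring in ``within``."""
        counts: dict[str, int] = {}
        for a, s, d, _bo in self.records:
            if within is not None and a not in within:
                continue
            for p in (s, d):
                if p != MISSING:
                    counts[p] = counts.get(p, 0) + 1
        return counts


def _toposort(records: list[tuple[str, str, str, int]]) -> list[tuple[str, str, str, int]]:
    """Kahn topological sort; ties broken by (birth_order, id).

    Raises :class:`PedigreeError` naming the animals on a cycle.
    """
    by_id = {r[0]: r for r in records}
    indeg = {r[0]: 0 for r in records}
    children: dict[str, list[str]] = {r[0]: [] for r in records}
    for a, s, d, _bo in records:
        for p in (s, d):
            if p != MISSING:
                if p not in by_id:
                    raise PedigreeError(f"parent {p!r} of {a!r} has no pedigree record")
                indeg[a] += 1
                children[p].append(a)

    import heapq

    ready = [( by_id[a][3], a) for a, k in indeg.items() if k == 0]
    heapq.heapify(ready)
    out: list[tuple[str, str, str, int]] = []
    while ready:
        _bo, a = heapq.heappop(ready)
        out.append(by_id[a])
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, (by_id[c][3], c))
    if len(out) != len(records):
        cyc = sorted(a for a, k in indeg.items() if k > 0)
        raise PedigreeError(f"pedigree contains a cycle involving: {cyc[:10]}")
    return out


# ---------------------------------------------------------------------------
# Numerator relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrices:
    """A and its partitions by genotyped status, in pedigree order.

    ``order`` lists the animal ids indexing the rows/columns of ``A``.  The
    partitions (filled by :func:`partition_A`) follow a single permutation
    putting genotyped animals first.
    """

    order: list[str]
    A: np.ndarray
    Ainv: np.ndarray | None = None
    genotyped: list[str] | None = None
    nongenotyped: list[str] | None = None
    Agg: np.ndarray | None = None
    Ang: np.ndarray | None = None
    Agn: np.ndarray | None = None
    Ann: np.ndarray | None = None

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.A) - 1.0


@njit(cache=True)
def _tabular_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:  # pragma: no cover
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            asj = A[j, s] if s >= 0 else 0.0
            adj = A[j, d] if d >= 0 else 0.0
            val = 0.5 * (asj + adj)
            A[i, j] = val
            A[j, i] = val
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return A


def compute_A(pedigree: Pedigree) -> RelationshipMatrices:
    """Numerator relationship matrix by the tabular method with inbreeding.

    ``a_ij = 0.5 (a_{j,sire(i)} + a_{j,dam(i)})`` for j preceding i, and
    ``a_ii = 1 + 0.5 a_{sire(i),dam(i)}``; a missing parent contributes 0.
    """
    sire, dam = pedigree.parent_arrays()
    A = _tabular_A(sire, dam)
    return RelationshipMatrices(order=list(pedigree.ids), A=A)


def invert_A(pedigree: Pedigree) -> np.ndarray:
    """``A⁻¹`` by Henderson's rules with full inbreeding accounting.

    Mendelian-sampling variances ``d_i`` use the parental inbreeding
    coefficients taken from the tabular ``A`` diagonal, so the result equals
    the direct inverse of :func:`compute_A` output (to numerical precision).
    """
    rel = compute_A(pedigree)
    F = rel.inbreeding()
    sire, dam = pedigree.parent_arrays()
    n = pedigree.n
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            mend = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mend = 0.75 - 0.25 * F[p]
        else:
            mend = 1.0
        alpha = 1.0 / mend
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[p, i] -= alpha / 2.0
                Ainv[i, p] -= alpha / 2.0
                for p2 in (s, d):
                    if p2 >= 0:
                        Ainv[p, p2] += alpha / 4.0
    return Ainv


def partition_A(rel: RelationshipMatrices, genotyped_ids: set[str]) -> RelationshipMatrices:
    """Partition ``A`` into genotyped/non-genotyped blocks.

    Returns a new :class:`RelationshipMatrices` carrying ``Agg, Ang, Agn,
    Ann`` under the single permutation that lists genotyped animals first
    (each group in pedigree order).
    """
    if not genotyped_ids:
        raise ValueError("empty genotyped set: single-step partition undefined")
    missing = genotyped_ids - set(rel.order)
    if missing:
        raise ValueError(f"genotyped ids absent from pedigree: {sorted(missing)[:5]}")
    g = [a for a in rel.order if a in genotyped_ids]
    n_ = [a for a in rel.order if a not in genotyped_ids]
    idx = {a: i for i, a in enumerate(rel.order)}
    gi = np.array([idx[a] for a in g], dtype=int)
    ni = np.array([idx[a] for a in n_], dtype=int)
    A = rel.A
    return RelationshipMatrices(
        order=list(rel.order),
        A=A,
        Ainv=rel.Ainv,
        genotyped=g,
        nongenotyped=n_,
        Agg=A[np.ix_(gi, gi)],
        Ang=A[np.ix_(ni, gi)],
        Agn=A[np.ix_(gi, ni)],
        Ann=A[np.ix_(ni, ni)],
    )


# ---------------------------------------------------------------------------
# Breed composition and heterosis
# ---------------------------------------------------------------------------

@dataclass
class BreedComposition:
    """Per-animal breed-group fractions (saanen, anto, unknown), summing to 1."""

    fractions: dict[str, np.ndarray]

    def row(self, animal: str) -> np.ndarray:
        return self.fractions[animal]

    def matrix(self, animals: list[str]) -> np.ndarray:
        """Rows of fractions in BREED_GROUPS order for the given animals."""
        return np.array([self.fractions[a] for a in animals])


_UNKNOWN = np.array([0.0, 0.0, 1.0])


def breed_composition(pedigree: Pedigree) -> BreedComposition:
    """Breed fractions by recursion down the sorted pedigree.

    A founder with a recorded breed label is pure for that group; a founder
    with no label, and the contribution of any missing parent, is all
    "unknown".  Every non-founder is the average of its two parental rows.
    """
    fr: dict[str, np.ndarray] = {}
    for a, s, d, _bo in pedigree.records:
        if s == MISSING and d == MISSING:
            label = pedigree.founder_breeds.get(a)
            if label is None:
                fr[a] = _UNKNOWN.copy()
            else:
                v = np.zeros(3)
                v[BREED_GROUPS.index(label)] = 1.0
                fr[a] = v
        else:
            ps = fr[s] if s != MISSING else _UNKNOWN
            pd_ = fr[d] if d != MISSING else _UNKNOWN
            fr[a] = 0.5 * (ps + pd_)
    return BreedComposition(fractions=fr)


def heterosis(composition: BreedComposition, animal: str) -> float:
    """General heterosis covariate ``1 − Σ_j d_j²`` over the breed groups.

    Zero for a purebred; 0.5 for an F1 between two pure groups; bounded above
    by ``1 − 1/3`` for three groups.
    """
    d = composition.row(animal)
    return float(1.0 - np.sum(d * d))


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def read_pedigree_csv(path) -> Pedigree:
    """Read a pedigree CSV with columns animal,sire,dam,birth_order,breed.

    Empty sire/dam = missing parent; ``breed`` is only honoured for founders
    (empty = unknown).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"animal", "sire", "dam", "birth_order"}
    if not need <= set(df.columns):
        raise ValueError(f"pedigree CSV needs columns {sorted(need)}, got {list(df.columns)}")
    records = [
        (r.animal, r.sire, r.dam, int(r.birth_order)) for r in df.itertuples()
    ]
    founder_breeds = {}
    if "breed" in df.columns:
        for r in df.itertuples():
            if r.sire == MISSING and r.dam == MISSING and r.breed != MISSING:
                founder_breeds[r.animal] = r.breed
    return Pedigree(records=records, founder_breeds=founder_breeds)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    rows = []
    for a, s, d, bo in pedigree.records:
        rows.append(
            {
                "animal": a,
                "sire": s,
                "dam": d,
                "birth_order": bo,
                "breed": pedigree.founder_breeds.get(a, "")
                if (s == MISSING and d == MISSING)
                else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
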