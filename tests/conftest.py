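import numpy as np
import pytest

from goatbv import Pedigree, SimulationConfig, simulate_herd


@pytest.fixture
def trio() -> Pedigree:
    """Sire, dam, offspring; parents purebred of different groups."""
    return Pedigree(
        records=[("S", "", "", 0), ("D", "", "", 1), ("O", "S", "D", 2)],
        founder_breeds={"S": "saanen", "D": "anto"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160101)


def random_pedigree(rng: np.random.Generator, n: int, p_missing: float = 0.15) -> Pedigree:
    """A random valid pedigree of n animals; parents precede offspring."""
    records = []
    breeds = {}
    labels = ("saanen", "anto")
    for i in range(n):
        a = f"X{i:03d}"
        if i < 2 or rng.random() < 0.25:
            records.append((a, "", "", i))
            if rng.random() < 0.8:
                breeds[a] = labels[rng.integers(2)]
        else:
            s = f"X{rng.integers(i):03d}"
            d = f"X{rng.integers(i):03d}"
            while d == s:
                d = f"X{rng.integers(i):03d}"
            if rng.random() < p_missing:
                s = ""
            if rng.random() < p_missing:
                d = ""
            records.append((a, s, d, i))
    return Pedigree(records=records, founder_breeds=breeds)


def small_sim_config(seed: int = 101, **kw) -> SimulationConfig:
    """A desk-size herd used by the slower integration tests."""
    defaults = dict(
        n_does=220,
        n_sires=18,
        n_founder_dams=140,
        n_markers=240,
        n_qtl=10,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_herd():
    return simulate_herd(small_sim_config())

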