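"""Run configuration: trait variance priors, sampler controls, validation knobs.

Variance components are treated as known inputs ("parametric values") for
both models — they were estimated once on a much larger population and are
never re-estimated here.  Per trait the prior splits total additive genetic
variance into a residual polygenic part (fraction ``w``) and a marker-linked
part (fraction ``1 − w``); the mixture-prior null probability π is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: Per-trait (polygenic variance, SNP variance, residual variance).
#: Units: kg² for yields, log2² for somatic cell score.
TRAIT_PRIORS: dict[str, tuple[float, float, float]] = {
    "milk": (9098.6, 1011.0, 30345.0),
    "fat": (8.66, 1.33, 35.20),
    "protein": (5.69, 0.88, 23.10),
    "scs": (0.51, 0.08, 2.50),
}

DEFAULT_PI = 0.98


@dataclass
class TraitVariances:
    """Variance components for one trait."""

    polygenic: float
    snp: float
    residual: float

    @property
    def total_genetic(self) -> float:
        return self.polygenic + self.snp

    @property
    def w(self) -> float:
        """Fraction of genetic variance assigned to the residual polygenic
        effect (≈0.86–0.90 for the default traits)."""
        return self.polygenic / self.total_genetic

    @property
    def h2(self) -> float:
        return self.total_genetic / (self.total_genetic + self.residual)

    @classmethod
    def for_trait(cls, trait: str) -> "TraitVariances":
        p, s, e = TRAIT_PRIORS[trait]
        return cls(polygenic=p, snp=s, residual=e)


@dataclass
class ChainConfig:
    """MCMC controls: 50,000 iterations with 1,000 burned in by default;
    every 10th retained draw is stored."""

    length: int = 50_000
    burn_in: int = 1_000
    thin: int = 10
    seed: int = 2016

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.length):
            raise ValueError("burn_in must be smaller than chain length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class RunConfig:
    """Top-level configuration for the evaluation pipeline."""

    trait: str = "milk"
    variances: TraitVariances | None = None
    pi: float = DEFAULT_PI
    w: float | None = None  # None → derived from the variance components
    fixed_variances: bool = True
    chain: ChainConfig = field(default_factory=ChainConfig)
    training_fraction: float = 0.7
    min_sire_progeny: int = 5
    min_dam_lactations: int = 1
    seed: int = 2016

    def __post_init__(self) -> None:
        if self.variances is None:
            self.variances = TraitVariances.for_trait(self.trait)
        if self.w is None:
            self.w = self.variances.w

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "variances" in d and isinstance(d["variances"], dict):
            d["variances"] = TraitVariances(**d["variances"])
        if "chain" in d and isinstance(d["chain"], dict):
            d["chain"] = ChainConfig(**d["chain"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
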