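"""Core domain types shared across the package.

The twin-model types parameterize a bivariate phenotype: one continuous
trait and one binary diagnosis treated as a thresholded standard-normal
liability.  Variance of each latent phenotype is partitioned into additive
genetic (A), nonadditive genetic (D), shared environment (C) and nonshared
environment (E) components; cross-phenotype overlap is carried by one
correlation per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

ZYGOSITY_GROUPS = ("MZM", "DZM", "MZF", "DZF", "DZOS")
MZ_GROUPS = ("MZM", "MZF")
DZ_GROUPS = ("DZM", "DZF", "DZOS")
AGE_COHORTS = (9, 12, 15, 18)


@dataclass
class VarianceComponents:
    """Standardized variance shares of one latent phenotype.

    a2 + d2 + c2 + e2 must equal 1; C and D are not jointly identified in a
    twin-only design, so at most one of them may be positive.  ``s`` is a
    reciprocal sibling-interaction path between co-twins' phenotypes,
    applied on top of the latent decomposition.
    """

    a2: float = 0.0
    d2: float = 0.0
    c2: float = 0.0
    e2: float = 1.0
    s: float = 0.0

    def validate(self) -> "VarianceComponents":
        for name in ("a2", "d2", "c2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.e2 <= 0:
            raise ValueError("e2 must be > 0")
        if abs(self.a2 + self.d2 + self.c2 + self.e2 - 1.0) > 1e-8:
            raise ValueError("variance components must sum to 1")
        if self.c2 > 0 and self.d2 > 0:
            raise ValueError("C and D cannot both be positive in one model")
        if not -1.0 < self.s < 1.0:
            raise ValueError("sibling interaction s must lie in (-1, 1)")
        return self


@dataclass
class EtiologicCorrelations:
    """Correlations between the two phenotypes' A/D/C/E factors."""

    rA: float = 0.0
    rD: float = 0.0
    rC: float = 0.0
    rE: float = 0.0

    def validate(self) -> "EtiologicCorrelations":
        for name in ("rA", "rD", "rC", "rE"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        return self


@dataclass
class ThresholdSet:
    """Sex-specific liability thresholds on the standard-normal scale."""

    tau_m: float
    tau_f: float

    def validate(self) -> "ThresholdSet":
        for v in (self.tau_m, self.tau_f):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")
        return self

    def for_sex(self, sex: str) -> float:
        return self.tau_m if sex == "M" else self.tau_f

    @classmethod
    def from_prevalence(cls, prev_m: float, prev_f: float | None = None) -> "ThresholdSet":
        if prev_f is None:
            prev_f = prev_m
        for p in (prev_m, prev_f):
            if not 0.0 < p < 1.0:
                raise ValueError("prevalence must lie in (0, 1)")
        return cls(tau_m=float(norm.isf(prev_m)), tau_f=float(norm.isf(prev_f)))


@dataclass
class BivariateTwinSpec:
    """Generating model for one (continuous trait, binary diagnosis) pairing."""

    trait: VarianceComponents
    liability: VarianceComponents
    corr: EtiologicCorrelations
    thresholds: ThresholdSet
    n_pairs: dict[str, int] = field(
        default_factory=lambda: {g: 2000 for g in ZYGOSITY_GROUPS}
    )
    trait_missing_rate: float = 0.0
    diagnosis_missing_rate: float = 0.0
    trait_name: str = "trait"
    diagnosis_name: str = "dx"
    age_cohort: int = 9
    seed: int = 0

    def validate(self) -> "BivariateTwinSpec":
        self.trait.validate()
        self.liability.validate()
        self.corr.validate()
        self.thresholds.validate()
        for g, n in self.n_pairs.items():
            if g not in ZYGOSITY_GROUPS:
                raise ValueError(f"unknown zygosity group {g!r}")
            if n < 0:
                raise ValueError("pair counts must be >= 0")
        for r in (self.trait_missing_rate, self.diagnosis_missing_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("missingness rates must lie in [0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        return self


@dataclass
class PolygenicSpec:
    """Generating model for genotypes, a discovery GWAS and a scored outcome.

    Genotypes are drawn under Hardy-Weinberg equilibrium with block-diagonal
    LD (Gaussian copula with ``ld_rho`` inside blocks of ``ld_block_size``
    variants).  ``h2_score`` is the proportion of outcome variance explained
    by the true polygenic score; ``fst`` optionally splits the sample into
    two subpopulations with divergent allele frequencies to create
    stratification confounding.
    """

    m_variants: int = 200
    n_causal: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    effect_sd: float = 0.1
    n_discovery: int = 50_000
    h2_score: float = 0.05
    fst: float = 0.0
    confound_shift: float = 0.0
    outcome_prevalence: float = 0.05
    seed: int = 0

    def validate(self) -> "PolygenicSpec":
        if self.n_causal > self.m_variants:
            raise ValueError("n_causal cannot exceed m_variants")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.h2_score <= 1.0:
            raise ValueError("h2_score must lie in [0, 1]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        return self


@dataclass
class ClumpSpec:
    """Greedy LD-clumping parameters."""

    r2: float = 0.1
    window_kb: float = 250.0
    p_ceiling: float = 1.0

    def validate(self) -> "ClumpSpec":
        if not 0.0 < self.r2 <= 1.0:
            raise ValueError("r2 must lie in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")
        return self


def to_dict(obj) -> dict:
    """Plain-dict view of any spec dataclass (for YAML/JSON round-trips)."""
    return asdict(obj)
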