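"""Synthetic twin cohorts with known ground truth.

Two generators live here:

* a bivariate twin-pair generator that draws (continuous trait, binary
  diagnosis liability) 4-vectors per pair from the model-implied cross-twin
  covariance of an ACE/ADE decomposition with optional reciprocal sibling
  interaction, then dichotomizes liabilities at sex-specific thresholds;
* an additive polygenic generator producing family-structured genotypes
  with block LD (Gaussian-copula haplotypes, Mendelian transmission so MZ
  co-twins are genetically identical and DZ co-twins share half their
  alleles in expectation), a noisy discovery GWAS over those variants, and
  an outcome whose variance explained by the true score is set exactly.

Everything is bit-reproducible from each generator's seed via named
substreams.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import substream
from .io import GenotypeData, PhenotypeTable
from .types import (
    ZYGOSITY_GROUPS,
    BivariateTwinSpec,
    PolygenicSpec,
)

__all__ = [
    "implied_moments",
    "simulate_twin_pairs",
    "draw_causal_effects",
    "simulate_genotypes",
    "simulate_discovery_sumstats",
    "attach_genetic_phenotype",
]

# cross-twin factor correlations (kappa) by zygosity class
_KAPPA = {"MZ": {"A": 1.0, "D": 1.0, "C": 1.0},
          "DZ": {"A": 0.5, "D": 0.25, "C": 1.0}}

_GROUP_SEXES = {"MZM": ("M", "M"), "DZM": ("M", "M"),
                "MZF": ("F", "F"), "DZF": ("F", "F"), "DZOS": ("M", "F")}


class ParameterError(ValueError):
    """Parameter combination implies a non-PSD covariance."""


def implied_moments(spec: BivariateTwinSpec, zygosity: str) -> np.ndarray:
    """Model-implied 4x4 correlation matrix (trait1, liab1, trait2, liab2).

    The latent decomposition gives cross-twin factor correlations of 1/0.5
    (A), 1/0.25 (D) and 1/1 (C) for MZ/DZ pairs, with E uncorrelated across
    co-twins.  Sibling interaction enters as mutual phenotype-on-phenotype
    paths s between co-twins' same-phenotype variables: with path matrix B,
    the observed covariance is (I-B)^-1 Sigma_latent (I-B)^-T, standardized
    back to a correlation matrix.
    """
    if zygosity not in ("MZ", "DZ"):
        raise ValueError("zygosity must be 'MZ' or 'DZ'")
    spec.validate()
    kap = _KAPPA[zygosity]
    t, l, c = spec.trait, spec.liability, spec.corr

    rw = (c.rA * np.sqrt(t.a2 * l.a2) + c.rD * np.sqrt(t.d2 * l.d2)
          + c.rC * np.sqrt(t.c2 * l.c2) + c.rE * np.sqrt(t.e2 * l.e2))
    x_tt = kap["A"] * t.a2 + kap["D"] * t.d2 + kap["C"] * t.c2
    x_ll = kap["A"] * l.a2 + kap["D"] * l.d2 + kap["C"] * l.c2
    x_tl = (kap["A"] * c.rA * np.sqrt(t.a2 * l.a2)
            + kap["D"] * c.rD * np.sqrt(t.d2 * l.d2)
            + kap["C"] * c.rC * np.sqrt(t.c2 * l.c2))
    sigma = np.array([
        [1.0, rw, x_tt, x_tl],
        [rw, 1.0, x_tl, x_ll],
        [x_tt, x_tl, 1.0, rw],
        [x_tl, x_ll, rw, 1.0],
    ])
    if t.s != 0.0 or l.s != 0.0:
        b = np.zeros((4, 4))
        b[0, 2] = b[2, 0] = t.s
        b[1, 3] = b[3, 1] = l.s
        inv = np.linalg.inv(np.eye(4) - b)
        sigma = inv @ sigma @ inv.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    if np.linalg.eigvalsh(sigma)[0] < -1e-9:
        raise ParameterError(
            f"implied {zygosity} matrix is not positive semidefinite"
        )
    return sigma


def simulate_twin_pairs(spec: BivariateTwinSpec) -> PhenotypeTable:
    """Draw a phenotype table of twin pairs from the implied moments."""
    spec.validate()
    rng = substream(spec.seed, "twin_pairs")
    moments = {z: implied_moments(spec, z) for z in ("MZ", "DZ")}
    chol = {z: np.linalg.cholesky(m + 1e-12 * np.eye(4))
            for z, m in moments.items()}
    rows = []
    for group in ZYGOSITY_GROUPS:
        n = spec.n_pairs.get(group, 0)
        if n == 0:
            continue
        zyg_class = "MZ" if group.startswith("MZ") else "DZ"
        z = rng.standard_normal((n, 4)) @ chol[zyg_class].T
        sexes = _GROUP_SEXES[group]
        taus = [spec.thresholds.for_sex(s) for s in sexes]
        t1, t2 = z[:, 0], z[:, 2]
        y1 = (z[:, 1] > taus[0]).astype(float)
        y2 = (z[:, 3] > taus[1]).astype(float)
        if spec.trait_missing_rate > 0:
            miss = rng.random((n, 2)) < spec.trait_missing_rate
            t1 = np.where(miss[:, 0], np.nan, t1)
            t2 = np.where(miss[:, 1], np.nan, t2)
        if spec.diagnosis_missing_rate > 0:
            miss = rng.random((n, 2)) < spec.diagnosis_missing_rate
            y1 = np.where(miss[:, 0], np.nan, y1)
            y2 = np.where(miss[:, 1], np.nan, y2)
        pair_ids = [f"{group}_{i:06d}" for i in range(n)]
        for order, sex, tt, yy in ((1, sexes[0], t1, y1), (2, sexes[1], t2, y2)):
            rows.append(pd.DataFrame({
                "pair_id": pair_ids,
                "twin_order": order,
                "zygosity": group,
                "sex": sex,
                "age_cohort": spec.age_cohort,
                spec.trait_name: tt,
                spec.diagnosis_name: yy,
            }))
    if not rows:
        df = pd.DataFrame(columns=["pair_id", "twin_order", "zygosity", "sex",
                                   "age_cohort", spec.trait_name,
                                   spec.diagnosis_name])
    else:
        df = pd.concat(rows, ignore_index=True)
        df = df.sort_values(["pair_id", "twin_order"], ignore_index=True)
    return PhenotypeTable(df=df, measures=[spec.trait_name],
                          diagnoses=[spec.diagnosis_name])


# ---------------------------------------------------------------------------
# polygenic generator
# ---------------------------------------------------------------------------

def draw_causal_effects(pspec: PolygenicSpec) -> np.ndarray:
    """Per-variant true effects: n_causal nonzero betas, zero elsewhere."""
    pspec.validate()
    rng = substream(pspec.seed, "causal_effects")
    betas = np.zeros(pspec.m_variants)
    causal = rng.choice(pspec.m_variants, size=pspec.n_causal, replace=False)
    betas[causal] = rng.normal(0.0, pspec.effect_sd, size=pspec.n_causal)
    return betas


def _haplotypes(rng, n_hap: int, thresholds: np.ndarray,
                block_size: int, rho: float) -> np.ndarray:
    """0/1 haplotypes via a block compound-symmetric Gaussian copula."""
    m = thresholds.size
    if rho == 0.0:
        z = rng.standard_normal((n_hap, m))
    else:
        z = np.empty((n_hap, m))
        for start in range(0, m, block_size):
            k = min(block_size, m - start)
            shared = rng.standard_normal((n_hap, 1))
            own = rng.standard_normal((n_hap, k))
            z[:, start:start + k] = (np.sqrt(rho) * shared
                                     + np.sqrt(1 - rho) * own)
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(
    pspec: PolygenicSpec, pairs: PhenotypeTable
) -> tuple[GenotypeData, dict]:
    """Family-structured genotypes for every individual in ``pairs``.

    Parents get copula-correlated haplotypes (block LD); each child inherits
    one whole haplotype per parent.  MZ co-twins receive identical genotypes;
    DZ co-twins redraw transmission, giving expected dosage correlation 0.5.
    Returns the genotypes plus a metadata dict with per-individual subpopulation
    labels and pooled allele1 frequencies.
    """
    pspec.validate()
    rng = substream(pspec.seed, "genotypes")
    m = pspec.m_variants
    lo, hi = pspec.maf_range
    base_freq = rng.uniform(lo, hi, size=m)

    if pspec.fst > 0:
        f = pspec.fst
        a = base_freq * (1 - f) / f
        b = (1 - base_freq) * (1 - f) / f
        pop_freq = np.stack([rng.beta(a, b), rng.beta(a, b)])
        pop_freq = np.clip(pop_freq, 1e-4, 1 - 1e-4)
    else:
        pop_freq = np.stack([base_freq, base_freq])

    pair_meta = (pairs.df[pairs.df["twin_order"] == 1]
                 [["pair_id", "zygosity"]].reset_index(drop=True))
    n_pairs = len(pair_meta)
    pair_pop = (rng.random(n_pairs) < 0.5).astype(int) if pspec.fst > 0 \
        else np.zeros(n_pairs, dtype=int)

    dosages = np.empty((2 * n_pairs, m), dtype=np.float64)
    ids: list[str] = []
    subpop: list[int] = []
    for pop in (0, 1):
        idx = np.flatnonzero(pair_pop == pop)
        if idx.size == 0:
            continue
        thresholds = norm.ppf(pop_freq[pop])
        # 4 parental haplotypes per pair
        haps = _haplotypes(rng, 4 * idx.size, thresholds,
                           pspec.ld_block_size, pspec.ld_rho)
        haps = haps.reshape(idx.size, 4, m)
        pick1 = rng.integers(0, 2, size=(idx.size, 2))  # child 1: pat, mat
        pick2 = rng.integers(0, 2, size=(idx.size, 2))  # child 2 if DZ
        rows = np.arange(idx.size)
        child1 = (haps[rows, pick1[:, 0], :]
                  + haps[rows, 2 + pick1[:, 1], :]).astype(float)
        child2_dz = (haps[rows, pick2[:, 0], :]
                     + haps[rows, 2 + pick2[:, 1], :]).astype(float)
        is_mz = pair_meta.loc[idx, "zygosity"].str.startswith("MZ").to_numpy()
        child2 = np.where(is_mz[:, None], child1, child2_dz)
        dosages[2 * idx, :] = child1
        dosages[2 * idx + 1, :] = child2
    for i in range(n_pairs):
        pid = pair_meta.loc[i, "pair_id"]
        ids.extend([f"{pid}_1", f"{pid}_2"])
        subpop.extend([pair_pop[i], pair_pop[i]])

    alleles1 = rng.choice(["A", "C"], size=m)
    alleles2 = rng.choice(["G", "T"], size=m)
    variants = pd.DataFrame({
        "id": [f"rs{j + 1}" for j in range(m)],
        "chrom": "1",
        "pos": 5000 * (np.arange(m) + 1),
        "allele1": alleles1,
        "allele2": alleles2,
    })
    geno = GenotypeData(ids=ids, variants=variants, dosages=dosages)
    meta = {
        "subpop": pd.Series(subpop, index=ids, name="subpop"),
        "maf": pop_freq.mean(axis=0),
    }
    return geno, meta


def simulate_discovery_sumstats(
    pspec: PolygenicSpec, variants: pd.DataFrame, maf: np.ndarray,
    truth: np.ndarray,
) -> pd.DataFrame:
    """Noisy marginal GWAS estimates of the true effects.

    SE follows the standard-error of a per-allele regression coefficient at
    the variant's allele frequency, sqrt(1 / (2 maf (1-maf) n)); the
    estimate is truth plus Gaussian noise at that SE and p comes from the
    two-sided Wald statistic.
    """
    pspec.validate()
    rng = substream(pspec.seed, "discovery_gwas")
    se = np.sqrt(1.0 / (2.0 * maf * (1.0 - maf) * pspec.n_discovery))
    beta_hat = truth + rng.normal(0.0, se)
    z = beta_hat / se
    p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "id": variants["id"].to_numpy(),
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": variants["allele1"].to_numpy(),
        "other_allele": variants["allele2"].to_numpy(),
        "beta": beta_hat,
        "se": se,
        "p": p,
        "n": pspec.n_discovery,
    })


def attach_genetic_phenotype(
    geno: GenotypeData, truth: np.ndarray, pspec: PolygenicSpec,
    subpop: pd.Series | None = None,
) -> pd.DataFrame:
    """Outcomes with a known polygenic architecture, indexed by individual id.

    The continuous outcome is sqrt(h2_score) times the standardized true
    score plus independent noise; the binary outcome thresholds the
    continuous one at its ``outcome_prevalence`` quantile.  If a subpop
    labelling and ``confound_shift`` are given, subpopulation 1 gets a mean
    shift, creating stratification confounding with no causal pathway when
    truth is all zero.
    """
    pspec.validate()
    rng = substream(pspec.seed, "outcome")
    g = geno.dosages @ truth
    sd = g.std(ddof=0)
    g_std = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    h2 = pspec.h2_score
    noise = rng.standard_normal(len(g))
    y = np.sqrt(h2) * g_std + np.sqrt(1.0 - h2) * noise
    if subpop is not None and pspec.confound_shift != 0.0:
        y = y + pspec.confound_shift * subpop.reindex(geno.ids).to_numpy()
    tau = np.quantile(y, 1.0 - pspec.outcome_prevalence)
    out = pd.DataFrame({
        "score_outcome": y,
        "score_dx": (y > tau).astype(int),
        "true_score": g_std,
    }, index=pd.Index(geno.ids, name="individual_id"))
    if subpop is not None:
        out["subpop"] = subpop.reindex(geno.ids).to_numpy()
    return out
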