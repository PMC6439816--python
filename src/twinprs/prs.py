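"""Polygenic risk scoring and cluster-robust association testing.

The pipeline mirrors standard PRS practice: harmonize discovery summary
statistics to the target genotypes, greedily LD-clump by p-value, sum
effect-allele dosages weighted by discovery effect sizes at each p-value
selection threshold, z-standardize, derive principal-component covariates
for population stratification, and test score-outcome associations with
generalized estimating equations whose sandwich variance clusters on twin
pair.  Benjamini-Hochberg FDR adjustment and diagnosed-individual
exclusion reruns complete the inferential surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from statsmodels.genmod.cov_struct import Independence
from statsmodels.stats.multitest import multipletests

from .io import GenotypeData
from .types import ClumpSpec

logger = logging.getLogger("twinprs")

DEFAULT_THRESHOLDS = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)
PRIMARY_THRESHOLD = 0.5

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


# ---------------------------------------------------------------------------
# harmonization and clumping
# ---------------------------------------------------------------------------

def harmonize_alleles(sumstats: pd.DataFrame, geno: GenotypeData) -> pd.DataFrame:
    """Match summary statistics to target variants by id and align alleles.

    Returns a weight table with one row per usable variant: the target
    column index, position, aligned beta (sign-flipped when the effect
    allele is the target's allele2) and discovery p-value.  Strand-ambiguous
    (A/T, C/G) and allele-mismatching variants are dropped; all drop counts
    are logged.  Zero overlap is an error.
    """
    tgt = geno.variants.reset_index(drop=True).copy()
    tgt["geno_idx"] = np.arange(len(tgt))
    merged = sumstats.merge(tgt[["id", "chrom", "pos", "allele1", "allele2",
                                 "geno_idx"]],
                            on="id", how="inner", suffixes=("", "_tgt"))
    n_absent = len(sumstats) - len(merged)
    if len(merged) == 0:
        raise ValueError("no overlap between summary statistics and target")
    ambiguous = [
        frozenset((ea, oa)) in _AMBIGUOUS
        for ea, oa in zip(merged["effect_allele"], merged["other_allele"])
    ]
    ambiguous = np.array(ambiguous)
    direct = ((merged["effect_allele"] == merged["allele1"])
              & (merged["other_allele"] == merged["allele2"])).to_numpy()
    flipped = ((merged["effect_allele"] == merged["allele2"])
               & (merged["other_allele"] == merged["allele1"])).to_numpy()
    mismatch = ~(direct | flipped)
    keep = ~ambiguous & ~mismatch
    n_flip = int((flipped & keep).sum())
    logger.info(
        "harmonize_alleles: %d matched (%d sign-flipped), %d ambiguous, "
        "%d mismatched, %d absent from target",
        int(keep.sum()), n_flip, int(ambiguous.sum()),
        int((mismatch & ~ambiguous).sum()), n_absent,
    )
    out = merged.loc[keep, ["id", "chrom", "pos", "geno_idx", "beta", "p"]].copy()
    out.loc[flipped[keep], "beta"] *= -1.0
    if len(out) == 0:
        raise ValueError("no variants usable after allele harmonization")
    return out.reset_index(drop=True)


def _imputed_dosages(geno: GenotypeData, idx: np.ndarray) -> np.ndarray:
    """Dosage columns with missing calls mean-imputed (2 x target freq)."""
    d = geno.dosages[:, idx].copy()
    freq = geno.allele_freq()[idx]
    nan = np.isnan(d)
    if nan.any():
        d[nan] = np.broadcast_to(2.0 * freq, d.shape)[nan]
    return d


def ld_clump(weights: pd.DataFrame, geno: GenotypeData,
             spec: ClumpSpec | None = None) -> pd.DataFrame:
    """Greedy p-value clumping against target-sample LD.

    Repeatedly takes the best remaining variant (ascending p, ties broken
    by position then id) as an index variant and removes all others on the
    same chromosome within the window whose squared correlation with it
    exceeds the threshold.  Output row order follows the input, so the
    result is invariant to input row order.
    """
    spec = (spec or ClumpSpec()).validate()
    w = weights[weights["p"] <= spec.p_ceiling].reset_index(drop=True)
    if len(w) == 0:
        return w
    order = w.sort_values(["p", "pos", "id"], kind="mergesort").index.to_numpy()
    x = _imputed_dosages(geno, w["geno_idx"].to_numpy())
    x = x - x.mean(axis=0)
    norms = np.sqrt((x ** 2).sum(axis=0))
    norms[norms == 0] = np.inf  # monomorphic: correlates with nothing
    x = x / norms
    chrom = w["chrom"].to_numpy()
    pos = w["pos"].to_numpy(dtype=float)
    window = spec.window_kb * 1000.0
    alive = np.ones(len(w), dtype=bool)
    index_set = np.zeros(len(w), dtype=bool)
    for i in order:
        if not alive[i]:
            continue
        index_set[i] = True
        near = (alive & (chrom == chrom[i])
                & (np.abs(pos - pos[i]) <= window))
        near[i] = False
        if near.any():
            r2 = (x[:, near].T @ x[:, i]) ** 2
            kill = np.flatnonzero(near)[r2 > spec.r2]
            alive[kill] = False
        alive[i] = False
    logger.info("ld_clump: %d index variants from %d", int(index_set.sum()),
                len(w))
    return w[index_set].reset_index(drop=True)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class PrsProfile:
    """Per-individual scores at each p-value selection threshold.

    ``zscores``/``raw`` are individual x threshold frames; ``n_variants``
    maps threshold -> number of variants contributing.
    """

    zscores: pd.DataFrame
    raw: pd.DataFrame
    n_variants: dict[float, int] = field(default_factory=dict)

    def z(self, threshold: float) -> pd.Series:
        return self.zscores[threshold]


def score_prs(geno: GenotypeData, weights: pd.DataFrame,
              thresholds=DEFAULT_THRESHOLDS) -> PrsProfile:
    """Weighted allele scores, z-standardized, at each threshold.

    score_i = sum_j beta_j dosage_ij over variants with discovery p below
    the threshold; missing dosages are imputed as twice the effect-allele
    frequency in the target sample.  The z-transform uses the sample SD
    (denominator n-1).  A threshold selecting no variants yields a flagged
    zero column.
    """
    thresholds = sorted(set(float(t) for t in thresholds))
    raw = {}
    nvar = {}
    idx = weights["geno_idx"].to_numpy()
    d = _imputed_dosages(geno, idx)
    betas = weights["beta"].to_numpy()
    pvals = weights["p"].to_numpy()
    for thr in thresholds:
        mask = pvals < thr
        nvar[thr] = int(mask.sum())
        if nvar[thr] == 0:
            logger.warning("score_prs: threshold %g selects no variants", thr)
            raw[thr] = np.zeros(geno.n_individuals)
        else:
            raw[thr] = d[:, mask] @ betas[mask]
    raw_df = pd.DataFrame(raw, index=pd.Index(geno.ids, name="individual_id"))
    z_df = raw_df.copy()
    for thr in thresholds:
        sd = raw_df[thr].std(ddof=1)
        z_df[thr] = ((raw_df[thr] - raw_df[thr].mean()) / sd
                     if sd > 0 else 0.0)
    return PrsProfile(zscores=z_df, raw=raw_df, n_variants=nvar)


class PrsScorer(BaseEstimator):
    """Clump-and-threshold polygenic scorer.

    ``fit`` harmonizes the summary statistics to a reference genotype panel
    and LD-clumps them; ``transform`` scores any genotype set on the
    retained weights at every threshold.
    """

    def __init__(self, thresholds=DEFAULT_THRESHOLDS,
                 clump: ClumpSpec | None = None, do_clump: bool = True):
        self.thresholds = thresholds
        self.clump = clump
        self.do_clump = do_clump

    def fit(self, geno: GenotypeData, sumstats: pd.DataFrame):
        w = harmonize_alleles(sumstats, geno)
        if self.do_clump:
            w = ld_clump(w, geno, self.clump)
        self.weights_ = w
        return self

    def transform(self, geno: GenotypeData) -> PrsProfile:
        return score_prs(geno, self.weights_, self.thresholds)

    def fit_transform(self, geno: GenotypeData,
                      sumstats: pd.DataFrame) -> PrsProfile:
        return self.fit(geno, sumstats).transform(geno)


# ---------------------------------------------------------------------------
# stratification covariates
# ---------------------------------------------------------------------------

class GenotypePCA(BaseEstimator):
    """Principal components of the scaled genotype matrix.

    Variants are MAF-filtered and greedily LD-pruned (r^2 against kept
    variants inside a sliding window), then centered and scaled by
    1/sqrt(2f(1-f)).  Components are fitted on a deduplicated individual
    set (pass ``exclude`` to drop one twin of each MZ pair, whose genotypes
    are identical) and scores are produced for everyone, so MZ co-twins
    receive equal PCs by construction.  Scores are whitened (unit variance,
    mutually orthogonal on the fit sample) and signed so the
    largest-magnitude loading of each component is positive.
    """

    def __init__(self, n_components: int = 10, maf_min: float = 0.05,
                 prune_window: int = 50, prune_r2: float = 0.2):
        self.n_components = n_components
        self.maf_min = maf_min
        self.prune_window = prune_window
        self.prune_r2 = prune_r2

    def _scaled(self, geno: GenotypeData) -> np.ndarray:
        d = _imputed_dosages(geno, self.keep_idx_)
        return (d - 2.0 * self.freq_) / np.sqrt(
            2.0 * self.freq_ * (1.0 - self.freq_))

    def fit(self, geno: GenotypeData, exclude: set[str] | None = None):
        freq = geno.allele_freq()
        maf = np.minimum(freq, 1.0 - freq)
        candidates = np.flatnonzero(maf >= self.maf_min)
        d = _imputed_dosages(geno, candidates)
        d = d - d.mean(axis=0)
        norms = np.sqrt((d ** 2).sum(axis=0))
        norms[norms == 0] = np.inf
        d = d / norms
        kept: list[int] = []
        for j in range(len(candidates)):
            recent = [k for k in kept[-self.prune_window:]]
            if recent:
                r2 = (d[:, recent].T @ d[:, j]) ** 2
                if (r2 > self.prune_r2).any():
                    continue
            kept.append(j)
        self.keep_idx_ = candidates[kept]
        if len(self.keep_idx_) < self.n_components:
            raise ValueError(
                f"only {len(self.keep_idx_)} variants after pruning; "
                f"cannot extract {self.n_components} components")
        self.freq_ = freq[self.keep_idx_]
        x = self._scaled(geno)
        rows = np.ones(len(geno.ids), dtype=bool)
        if exclude:
            rows = ~np.isin(geno.ids, list(exclude))
        if rows.sum() < self.n_components:
            raise ValueError("fewer fit individuals than components")
        self._pca = PCA(n_components=self.n_components, whiten=True,
                        svd_solver="full", random_state=0)
        self._pca.fit(x[rows])
        # sign convention: largest-magnitude loading positive
        comp = self._pca.components_
        signs = np.sign(comp[np.arange(comp.shape[0]),
                             np.argmax(np.abs(comp), axis=1)])
        signs[signs == 0] = 1.0
        self._signs = signs
        self.loadings_ = comp * signs[:, None]
        return self

    def transform(self, geno: GenotypeData) -> pd.DataFrame:
        x = self._scaled(geno)
        scores = self._pca.transform(x) * self._signs[None, :]
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(scores, index=pd.Index(geno.ids,
                                                   name="individual_id"),
                            columns=cols)

    def fit_transform(self, geno: GenotypeData,
                      exclude: set[str] | None = None) -> pd.DataFrame:
        return self.fit(geno, exclude=exclude).transform(geno)


def pca_covariates(geno: GenotypeData, k: int = 10,
                   exclude: set[str] | None = None, **kwargs) -> pd.DataFrame:
    """Top-k stratification PCs for every individual."""
    return GenotypePCA(n_components=k, **kwargs).fit_transform(
        geno, exclude=exclude)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

@dataclass
class GeeResult:
    """One score-outcome association with cluster-robust inference."""

    outcome: str
    family: str
    beta: float
    se: float
    p: float
    n: int
    n_clusters: int
    r2: float
    threshold: float | None = None
    or_: float | None = None
    or_ci: tuple[float, float] | None = None
    p_fdr: float | None = None
    excluded: bool = False

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome, "family": self.family,
            "threshold": self.threshold, "beta": self.beta, "se": self.se,
            "p": self.p, "p_fdr": self.p_fdr, "r2": self.r2, "n": self.n,
            "n_clusters": self.n_clusters, "excluded": self.excluded,
        }
        if self.family == "logistic":
            d["OR"] = self.or_
            d["OR_lo"], d["OR_hi"] = self.or_ci
        return d


def gee_associate(outcome, prs, covariates=None, clusters=None,
                  family: str = "linear", outcome_name: str = "outcome",
                  threshold: float | None = None,
                  excluded: bool = False) -> GeeResult:
    """Score-outcome regression with a pair-clustered sandwich variance.

    Uses estimating equations with an independence working correlation, so
    point estimates equal the ordinary GLM fit while standard errors sum
    score contributions within clusters (twin pairs).  For logistic models
    the effect is reported as an odds ratio with exp(beta +- 1.96 SE)
    limits.  R^2 is the incremental variance explained by the score over
    the covariates: a plain delta-R^2 for linear outcomes and the delta of
    the squared correlation between outcome and fitted probability for
    logistic ones (a documented proxy).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(prs, dtype=float)
    n_total = len(y)
    cov = (np.asarray(covariates, dtype=float)
           if covariates is not None else np.empty((n_total, 0)))
    if cov.ndim == 1:
        cov = cov[:, None]
    groups = (np.asarray(clusters) if clusters is not None
              else np.arange(n_total))
    ok = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(cov), axis=1)
    y, x, cov, groups = y[ok], x[ok], cov[ok], groups[ok]
    n = len(y)
    k_params = 2 + cov.shape[1]
    if n < 10 * k_params:
        raise ValueError(
            f"{n} complete cases for {k_params} parameters; need >= 10x")
    exog_full = np.column_stack([np.ones(n), x, cov])
    exog_base = np.column_stack([np.ones(n), cov])
    fam = (sm.families.Gaussian() if family == "linear"
           else sm.families.Binomial())
    if family == "logistic":
        for lvl in (0.0, 1.0):
            sub = y == lvl
            if sub.sum() and (x[sub].min() == x[sub].max()):
                raise ValueError(
                    "possible separation: score constant within an outcome "
                    "level")
    res = sm.GEE(y, exog_full, groups=groups, family=fam,
                 cov_struct=Independence()).fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    p = float(res.pvalues[1])
    res_base = sm.GEE(y, exog_base, groups=groups, family=fam,
                      cov_struct=Independence()).fit()
    if family == "linear":
        rss_full = float(np.sum((y - res.fittedvalues) ** 2))
        rss_base = float(np.sum((y - res_base.fittedvalues) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = (rss_base - rss_full) / tss if tss > 0 else np.nan
    else:
        def _sqcorr(fitted):
            if np.std(fitted) == 0 or np.std(y) == 0:
                return 0.0
            return float(np.corrcoef(y, fitted)[0, 1] ** 2)
        r2 = _sqcorr(res.fittedvalues) - _sqcorr(res_base.fittedvalues)
    result = GeeResult(
        outcome=outcome_name, family=family, beta=beta, se=se, p=p,
        n=n, n_clusters=int(pd.Series(groups).nunique()), r2=r2,
        threshold=threshold, excluded=excluded,
    )
    if family == "logistic":
        result.or_ = float(np.exp(beta))
        result.or_ci = (float(np.exp(beta - 1.96 * se)),
                        float(np.exp(beta + 1.96 * se)))
    return result


def exclude_diagnosed(df: pd.DataFrame, diagnosis: str) -> pd.DataFrame:
    """Drop individuals (not whole pairs) carrying the diagnosis."""
    dx = pd.to_numeric(df[diagnosis])
    keep = ~(dx == 1)
    n_dropped = int((~keep).sum())
    logger.info("exclude_diagnosed: removed %d of %d individuals (%s)",
                n_dropped, len(df), diagnosis)
    return df[keep]


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
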