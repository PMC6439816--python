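"""Joint categorical/continuous bivariate twin models.

A continuous trait and a binary diagnosis are modeled together per twin
pair: the diagnosis is the indicator that a standard-normal liability
exceeds a sex-specific threshold, and the 4-vector (trait twin 1, liability
twin 1, trait twin 2, liability twin 2) is multivariate normal with a
covariance implied by an ACE or ADE decomposition (optionally with a
reciprocal sibling-interaction path).  The exact likelihood of a pair
factorizes as the normal density of the observed continuous components
times the conditional-normal rectangle probability of the observed binary
components; missing elements are marginalized out.

The module provides saturated (descriptive) correlation estimation
(Pearson / tetrachoric / polyserial under equality constraints across twin
order and zygosity), maximum-likelihood structural fits with BIC/LRT model
selection, probandwise concordances, and the decomposition of the
phenotypic correlation into per-component shares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from scipy.special import log_ndtr

from ._bvn import bvn_upper, rect_prob
from .io import PhenotypeTable
from .simulate import implied_moments
from .types import (
    BivariateTwinSpec,
    EtiologicCorrelations,
    ThresholdSet,
    VarianceComponents,
)

logger = logging.getLogger("twinprs")

_FAMILY_COMPONENTS = {
    "E": (),
    "AE": ("A",),
    "CE": ("C",),
    "ACE": ("A", "C"),
    "ADE": ("A", "D"),
}

_LOG_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def standardize_by_sex(values, sex, groups=None) -> np.ndarray:
    """Z-score within each sex stratum (optionally crossed with ``groups``).

    Missing values are preserved; the SD uses denominator n-1.  A stratum
    with fewer than 2 non-missing values or zero variance is an error.
    """
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    strata = sex if groups is None else (
        np.char.add(np.char.add(sex.astype(str), "|"),
                    np.asarray(groups).astype(str))
    )
    out = np.full_like(values, np.nan)
    for s in np.unique(strata):
        idx = strata == s
        v = values[idx]
        obs = v[~np.isnan(v)]
        if obs.size < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 observations")
        sd = obs.std(ddof=1)
        if sd == 0:
            raise ValueError(f"stratum {s!r} is constant")
        out[idx] = (v - obs.mean()) / sd
    return out


def estimate_thresholds(diagnoses, sex) -> ThresholdSet:
    """Liability thresholds from sex-specific prevalence, tau = Phi^-1(1-p).

    A sex with zero cases gets +inf (flagged by a warning); all-missing
    input is an error.
    """
    y = np.asarray(diagnoses, dtype=float)
    sex = np.asarray(sex)
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError("all diagnoses missing")
    taus = {}
    for s in ("M", "F"):
        idx = obs & (sex == s)
        if idx.sum() == 0:
            taus[s] = np.inf
            continue
        prev = y[idx].mean()
        if prev == 0.0:
            warnings.warn(f"no cases for sex {s}; threshold at +inf")
            taus[s] = np.inf
        elif prev == 1.0:
            warnings.warn(f"all cases for sex {s}; threshold at -inf")
            taus[s] = -np.inf
        else:
            taus[s] = float(norm.isf(prev))
    ts = ThresholdSet(tau_m=taus["M"], tau_f=taus["F"])
    return ts


def tetrachoric_corr(table) -> tuple[float, float]:
    """Tetrachoric correlation of a 2x2 count table, with its SE.

    ``table[i][j]`` counts pairs with (x, y) = (1-i, 1-j), i.e. the [0][0]
    cell is both-affected.  Thresholds come from the margins; rho maximizes
    the multinomial likelihood of the four cells under bivariate-normal
    quadrant probabilities.  A zero margin yields a boundary estimate with
    a warning.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    n = tab.sum()
    if n == 0:
        raise ValueError("empty table")
    px = tab[0].sum() / n   # P(x = 1)
    py = tab[:, 0].sum() / n
    if px in (0.0, 1.0) or py in (0.0, 1.0):
        warnings.warn("zero margin; tetrachoric correlation at boundary")
        return (0.0, np.nan)
    tx, ty = norm.isf(px), norm.isf(py)

    def negll(rho):
        p11 = bvn_upper(tx, ty, rho)
        p1x = norm.sf(tx)
        p1y = norm.sf(ty)
        probs = np.array([p11, p1x - p11, p1y - p11, 1 - p1x - p1y + p11])
        probs = np.clip(probs, _LOG_FLOOR, 1.0)
        return -float(tab.ravel() @ np.log(probs))

    res = optimize.minimize_scalar(negll, bounds=(-0.9999, 0.9999),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    rho = float(res.x)
    if rho > 0.999 or rho < -0.999:
        # re-check the true boundary
        if negll(np.sign(rho) * 0.999999) <= res.fun:
            warnings.warn("tetrachoric correlation at boundary")
            return (float(np.sign(rho)), np.nan)
    h = 1e-4
    d2 = (negll(rho + h) - 2 * res.fun + negll(rho - h)) / h**2
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
    return (rho, se)


def polyserial_corr(x, y) -> float:
    """Polyserial correlation of a continuous x with a binary y.

    MLE under the model (x, liability) bivariate normal with y = 1 when the
    liability exceeds a threshold set by the prevalence of y.  x is
    standardized internally; complete pairs only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError("need at least 10 complete pairs")
    if y.min() == y.max():
        raise ValueError("y must contain both levels")
    z = (x - x.mean()) / x.std(ddof=1)
    tau = norm.isf(y.mean())
    sign = 2.0 * y - 1.0  # +1 for cases, -1 for controls

    def negll(rho):
        s = np.sqrt(1.0 - rho * rho)
        return -float(np.sum(norm.logcdf(sign * (rho * z - tau) / s)))

    res = optimize.minimize_scalar(negll, bounds=(-0.9999, 0.9999),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    rho = float(res.x)
    if abs(rho) > 0.999:
        rho = float(np.sign(rho))
    return rho


def probandwise_concordance(table: PhenotypeTable, diagnosis: str) -> pd.DataFrame:
    """Probandwise concordance 2C/(2C+D) per zygosity class.

    C counts pairs with both co-twins affected, D pairs with exactly one;
    pairs with a missing diagnosis are excluded.  With no affected pairs the
    concordance is undefined (NaN).
    """
    wide = table.to_pairs(table.measures[0] if table.measures else diagnosis,
                          diagnosis)
    rows = []
    for zc, grp in wide.groupby("zyg_class"):
        y1, y2 = grp["y1"].to_numpy(), grp["y2"].to_numpy()
        ok = ~(np.isnan(y1) | np.isnan(y2))
        c = int(((y1 == 1) & (y2 == 1) & ok).sum())
        d = int((((y1 == 1) ^ (y2 == 1)) & ok).sum())
        conc = 2 * c / (2 * c + d) if (2 * c + d) > 0 else np.nan
        rows.append({"zyg_class": zc, "n_concordant": c, "n_discordant": d,
                     "concordance": conc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact pair likelihood
# ---------------------------------------------------------------------------

def joint_pair_loglik(sigma: np.ndarray, t1, t2, y1, y2,
                      tau1: float = 0.0, tau2: float = 0.0) -> float:
    """Exact log-likelihood of one twin pair's observed 4-vector.

    ``sigma`` is the implied 4x4 covariance over (trait1, liab1, trait2,
    liab2); ``t1``/``t2`` are trait values and ``y1``/``y2`` diagnosis
    indicators, any of which may be None/NaN (marginalized out).  ``tau1``
    and ``tau2`` are each twin's liability threshold.  Returns -inf for a
    non-PSD sigma.
    """
    sigma = np.asarray(sigma, dtype=float)
    vals = [t1, y1, t2, y2]
    obs = [v is not None and np.isfinite(v) for v in vals]
    c_idx = [i for i in (0, 2) if obs[i]]
    b_idx = [i for i in (1, 3) if obs[i]]
    if not c_idx and not b_idx:
        return 0.0
    try:
        np.linalg.cholesky(sigma[np.ix_(c_idx + b_idx, c_idx + b_idx)]
                           + 1e-12 * np.eye(len(c_idx) + len(b_idx)))
    except np.linalg.LinAlgError:
        logger.debug("non-PSD sigma in joint_pair_loglik")
        return -np.inf
    ll = 0.0
    if c_idx:
        scc = sigma[np.ix_(c_idx, c_idx)]
        tvec = np.array([vals[i] for i in c_idx], dtype=float)
        sign, logdet = np.linalg.slogdet(scc)
        if sign <= 0:
            return -np.inf
        quad = tvec @ np.linalg.solve(scc, tvec)
        ll += -0.5 * (len(c_idx) * np.log(2 * np.pi) + logdet + quad)
    if b_idx:
        sbb = sigma[np.ix_(b_idx, b_idx)]
        if c_idx:
            sbc = sigma[np.ix_(b_idx, c_idx)]
            scc = sigma[np.ix_(c_idx, c_idx)]
            tvec = np.array([vals[i] for i in c_idx], dtype=float)
            a = sbc @ np.linalg.inv(scc)
            mu = a @ tvec
            cov = sbb - a @ sbc.T
        else:
            mu = np.zeros(len(b_idx))
            cov = sbb
        taus = {1: tau1, 3: tau2}
        sd = np.sqrt(np.diag(cov))
        alphas = [(taus[i] - mu[j]) / sd[j] for j, i in enumerate(b_idx)]
        ys = [vals[i] for i in b_idx]
        if len(b_idx) == 1:
            p = norm.sf(alphas[0]) if ys[0] == 1 else norm.cdf(alphas[0])
        else:
            rho = cov[0, 1] / (sd[0] * sd[1])
            lo = [a if y == 1 else -np.inf for a, y in zip(alphas, ys)]
            hi = [np.inf if y == 1 else a for a, y in zip(alphas, ys)]
            p = float(rect_prob(lo[0], hi[0], lo[1], hi[1], rho))
        ll += float(np.log(max(p, _LOG_FLOOR)))
    return float(ll)


@dataclass
class _PatternGroup:
    """Pairs sharing a zygosity class and observation pattern."""

    zyg: str                    # "MZ" | "DZ"
    c_idx: tuple[int, ...]      # observed continuous positions (0/2)
    b_idx: tuple[int, ...]      # observed binary positions (1/3)
    y: tuple[int, ...]          # diagnosis values at b_idx
    sexes: tuple[str, ...]      # sex of the twin at each b_idx
    tvals: np.ndarray           # (n, len(c_idx))
    n: int


def _build_groups(wide: pd.DataFrame) -> list[_PatternGroup]:
    t1 = wide["t1"].to_numpy(float)
    t2 = wide["t2"].to_numpy(float)
    y1 = wide["y1"].to_numpy(float)
    y2 = wide["y2"].to_numpy(float)
    sex1 = wide["sex1"].to_numpy()
    sex2 = wide["sex2"].to_numpy()
    zc = wide["zyg_class"].to_numpy()
    key = pd.DataFrame({
        "zyg": zc,
        "o_t1": ~np.isnan(t1), "o_t2": ~np.isnan(t2),
        "y1": np.where(np.isnan(y1), -1, y1).astype(int),
        "y2": np.where(np.isnan(y2), -1, y2).astype(int),
        "s1": np.where(np.isnan(y1), "-", sex1),
        "s2": np.where(np.isnan(y2), "-", sex2),
    })
    groups = []
    for (zyg, o1, o2, v1, v2, s1, s2), idx in key.groupby(
            list(key.columns), sort=True).groups.items():
        if not (o1 or o2 or v1 >= 0 or v2 >= 0):
            continue
        c_idx = tuple(p for p, o in ((0, o1), (2, o2)) if o)
        b_idx, yv, sx = [], [], []
        if v1 >= 0:
            b_idx.append(1); yv.append(int(v1)); sx.append(s1)
        if v2 >= 0:
            b_idx.append(3); yv.append(int(v2)); sx.append(s2)
        cols = [arr for p, arr in ((0, t1), (2, t2)) if p in c_idx]
        tvals = (np.column_stack([c[idx] for c in cols])
                 if cols else np.empty((len(idx), 0)))
        groups.append(_PatternGroup(zyg=zyg, c_idx=c_idx, b_idx=tuple(b_idx),
                                    y=tuple(yv), sexes=tuple(sx),
                                    tvals=tvals, n=len(idx)))
    return groups


def _group_loglik(g: _PatternGroup, sigma: np.ndarray, tau: dict) -> float:
    """Summed log-likelihood of one pattern group under one sigma."""
    c_idx, b_idx = list(g.c_idx), list(g.b_idx)
    ll = 0.0
    if c_idx:
        scc = sigma[np.ix_(c_idx, c_idx)]
        sign, logdet = np.linalg.slogdet(scc)
        if sign <= 0:
            return -np.inf
        inv = np.linalg.inv(scc)
        quad = np.einsum("ni,ij,nj->n", g.tvals, inv, g.tvals)
        ll += np.sum(-0.5 * (len(c_idx) * np.log(2 * np.pi) + logdet + quad))
    if b_idx:
        sbb = sigma[np.ix_(b_idx, b_idx)]
        if c_idx:
            a = sigma[np.ix_(b_idx, c_idx)] @ np.linalg.inv(
                sigma[np.ix_(c_idx, c_idx)])
            mu = g.tvals @ a.T
            cov = sbb - a @ sigma[np.ix_(c_idx, b_idx)]
        else:
            mu = np.zeros((g.n, len(b_idx)))
            cov = sbb
        var = np.diag(cov).copy()
        if np.any(var <= 0):
            return -np.inf
        sd = np.sqrt(var)
        taus = np.array([tau[s] for s in g.sexes])
        alpha = (taus[None, :] - mu) / sd[None, :]
        if len(b_idx) == 1:
            sgn = 1.0 if g.y[0] == 1 else -1.0
            ll += float(np.sum(log_ndtr(-sgn * alpha[:, 0])))
        else:
            # each binary outcome contributes a half-infinite interval, so
            # the rectangle is a single orthant probability after sign flips
            rho = cov[0, 1] / (sd[0] * sd[1])
            s0 = 1.0 if g.y[0] == 1 else -1.0
            s1 = 1.0 if g.y[1] == 1 else -1.0
            p = bvn_upper(s0 * alpha[:, 0], s1 * alpha[:, 1], s0 * s1 * rho)
            ll += float(np.sum(np.log(np.clip(p, _LOG_FLOOR, None))))
    return ll


def _total_loglik(groups, sigma_mz, sigma_dz, tau_m, tau_f) -> float:
    tau = {"M": tau_m, "F": tau_f, "-": 0.0}
    total = 0.0
    for g in groups:
        sigma = sigma_mz if g.zyg == "MZ" else sigma_dz
        ll = _group_loglik(g, sigma, tau)
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


# ---------------------------------------------------------------------------
# saturated model
# ---------------------------------------------------------------------------

def _double_entry_pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Cross-twin Pearson r with means/variances equated across twin order."""
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        return (np.nan, int(a.size))
    x = np.concatenate([a, b])
    y = np.concatenate([b, a])
    r = float(np.corrcoef(x, y)[0, 1])
    return (r, int(a.size))


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if not np.isfinite(r) or n < 4 or abs(r) >= 1:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    half = norm.isf((1 - level) / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


class SaturatedTwinModel(BaseEstimator):
    """Descriptive correlations for one (trait, diagnosis) pairing.

    Estimates, under equality of means/variances across twin order and
    zygosity (continuous trait standardized by sex) and of thresholds across
    zygosity: the phenotypic trait-diagnosis polyserial correlation pooled
    over individuals, and per zygosity class (MZ pooled, DZ pooled including
    opposite-sex pairs) the cross-twin trait Pearson correlation, the
    cross-twin diagnosis tetrachoric correlation, and the cross-twin
    cross-trait polyserial correlation.

    Parameters
    ----------
    min_pairs : warn when a zygosity class has fewer pairs than this.
    standardize : z-score the trait by sex before estimating.
    """

    def __init__(self, min_pairs: int = 30, standardize: bool = True):
        self.min_pairs = min_pairs
        self.standardize = standardize

    def fit(self, table: PhenotypeTable, trait: str, diagnosis: str):
        df = table.df.copy()
        if self.standardize:
            df[trait] = standardize_by_sex(df[trait], df["sex"])
        work = PhenotypeTable(df=df, measures=[trait], diagnoses=[diagnosis])
        wide = work.to_pairs(trait, diagnosis)

        t_all = df[trait].to_numpy(float)
        y_all = pd.to_numeric(df[diagnosis]).to_numpy(float)
        self.rph_ = polyserial_corr(t_all, y_all)
        n_ind = int((~(np.isnan(t_all) | np.isnan(y_all))).sum())
        self.rph_ci_ = _fisher_ci(self.rph_, n_ind)

        self.class_estimates_ = {}
        for zc in ("MZ", "DZ"):
            grp = wide[wide["zyg_class"] == zc]
            if len(grp) == 0:
                self.class_estimates_[zc] = {
                    "trait_r": np.nan, "trait_ci": (np.nan, np.nan),
                    "diag_r": np.nan, "diag_se": np.nan,
                    "cross_r": np.nan, "cross_ci": (np.nan, np.nan),
                    "n_pairs": 0,
                }
                continue
            if len(grp) < self.min_pairs:
                warnings.warn(
                    f"{zc} class has only {len(grp)} pairs; estimates "
                    "will be unstable"
                )
            t1, t2 = grp["t1"].to_numpy(), grp["t2"].to_numpy()
            y1, y2 = grp["y1"].to_numpy(), grp["y2"].to_numpy()
            r_t, n_t = _double_entry_pearson(t1, t2)
            okc = ~(np.isnan(y1) | np.isnan(y2))
            tab = [[int(((y1 == 1) & (y2 == 1) & okc).sum()),
                    int(((y1 == 1) & (y2 == 0) & okc).sum())],
                   [int(((y1 == 0) & (y2 == 1) & okc).sum()),
                    int(((y1 == 0) & (y2 == 0) & okc).sum())]]
            # symmetrize the discordant cells (twin order is arbitrary)
            m = (tab[0][1] + tab[1][0]) / 2.0
            sym = np.array([[tab[0][0], m], [m, tab[1][1]]])
            try:
                r_d, se_d = tetrachoric_corr(sym)
            except ValueError:
                r_d, se_d = np.nan, np.nan
            x_cross = np.concatenate([t1, t2])
            y_cross = np.concatenate([y2, y1])
            try:
                r_x = polyserial_corr(x_cross, y_cross)
            except ValueError:
                r_x = np.nan
            n_x = int((~(np.isnan(x_cross) | np.isnan(y_cross))).sum()) // 2
            self.class_estimates_[zc] = {
                "trait_r": r_t, "trait_ci": _fisher_ci(r_t, n_t),
                "diag_r": r_d, "diag_se": se_d,
                "cross_r": r_x, "cross_ci": _fisher_ci(r_x, max(n_x, 4)),
                "n_pairs": int(len(grp)),
            }
        self.thresholds_ = estimate_thresholds(y_all, df["sex"])
        self.n_pairs_ = int(wide.shape[0])
        return self

    def to_frame(self) -> pd.DataFrame:
        """One row in the layout of a correlations summary table."""
        mz, dz = self.class_estimates_["MZ"], self.class_estimates_["DZ"]
        return pd.DataFrame([{
            "rPh": self.rph_,
            "rPh_lo": self.rph_ci_[0], "rPh_hi": self.rph_ci_[1],
            "trait_r_MZ": mz["trait_r"], "trait_r_DZ": dz["trait_r"],
            "diag_r_MZ": mz["diag_r"], "diag_r_DZ": dz["diag_r"],
            "cross_r_MZ": mz["cross_r"], "cross_r_DZ": dz["cross_r"],
            "n_pairs": self.n_pairs_,
        }])


def fit_saturated(table: PhenotypeTable, trait: str,
                  diagnosis: str, **kwargs) -> SaturatedTwinModel:
    return SaturatedTwinModel(**kwargs).fit(table, trait, diagnosis)


# ---------------------------------------------------------------------------
# structural model
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _props_from_raw(raw: np.ndarray) -> np.ndarray:
    """Stick-breaking: len(raw) free values -> len(raw)+1 proportions."""
    props = []
    rest = 1.0
    for r in raw:
        v = rest * _sigmoid(r)
        props.append(v)
        rest -= v
    props.append(rest)
    return np.array(props)


def _raw_from_props(props: np.ndarray) -> np.ndarray:
    raw = []
    rest = 1.0
    for v in props[:-1]:
        raw.append(_logit(v / rest if rest > 0 else 0.5))
        rest -= v
    return np.array(raw)


class BivariateTwinModel(BaseEstimator):
    """Maximum-likelihood joint continuous/liability twin model.

    Parameters
    ----------
    family : one of "E", "AE", "CE", "ACE", "ADE", optionally with an
        "-s" suffix (e.g. "ADE-s") to add a reciprocal sibling-interaction
        path; equivalent to passing ``sibling_interaction=True``.
    sibling_interaction : add a single interaction path s applied to both
        phenotypes ("both"), or restrict it via ``interaction_on``.
    interaction_on : "both" | "trait" | "liability".
    fixed : mapping of parameter names ("rA", "rC", "rD", "rE", "s") to
        pinned values, used for nested reductions tested by LRT.
    standardize : z-score the trait by sex before fitting (the model assumes
        unit-variance, zero-mean continuous margins).
    n_restarts : extra random restarts after the moment-based start.
    tol : relative convergence tolerance on the log-likelihood.

    Fitted attributes
    -----------------
    trait_vc_, liability_vc_ : VarianceComponents per phenotype.
    corr_ : EtiologicCorrelations.  thresholds_ : ThresholdSet.
    s_ : sibling interaction estimate (0 when absent).
    loglik_, n_params_, bic_, n_pairs_ : fit summaries.
    ra_ : additive-genetic correlation;  rg_ : total genetic correlation
        (A+D composite under ADE, equal to ra_ otherwise);  re_ : nonshared
        environment correlation;  rph_ : model-implied within-twin
        phenotypic (trait-liability) correlation;  shares_ : proportion of
        rph_ from each active component.
    """

    def __init__(self, family: str = "AE", sibling_interaction: bool = False,
                 interaction_on: str = "both",
                 fixed: dict | None = None, standardize: bool = True,
                 n_restarts: int = 2, tol: float = 1e-9, maxiter: int = 500):
        self.family = family
        self.sibling_interaction = sibling_interaction
        self.interaction_on = interaction_on
        self.fixed = fixed
        self.standardize = standardize
        self.n_restarts = n_restarts
        self.tol = tol
        self.maxiter = maxiter

    # -- parameter packing ---------------------------------------------------

    def _family(self) -> tuple[str, bool]:
        fam = self.family
        sib = self.sibling_interaction
        if fam.endswith("-s"):
            fam = fam[:-2]
            sib = True
        if fam not in _FAMILY_COMPONENTS:
            raise ValueError(f"unknown model family {self.family!r}")
        return fam, sib

    def _param_names(self) -> list[str]:
        fam, sib = self._family()
        comps = _FAMILY_COMPONENTS[fam]
        fixed = self.fixed or {}
        names = []
        for i in range(len(comps)):  # stick-breaking raws per phenotype
            names += [f"vt_{i}", f"vl_{i}"]
        for cname in comps:
            if f"r{cname}" not in fixed:
                names.append(f"r{cname}")
        if "rE" not in fixed:
            names.append("rE")
        if sib and "s" not in fixed:
            names.append("s")
        names += ["tau_m", "tau_f"]
        return names

    def _unpack(self, x: np.ndarray):
        fam, sib = self._family()
        comps = _FAMILY_COMPONENTS[fam]
        fixed = self.fixed or {}
        names = self._param_names()
        vals = dict(zip(names, x))
        k = len(comps)
        pt = _props_from_raw(np.array([vals[f"vt_{i}"] for i in range(k)]))
        pl = _props_from_raw(np.array([vals[f"vl_{i}"] for i in range(k)]))
        vt = {c: pt[i] for i, c in enumerate(comps)}
        vt["E"] = pt[-1]
        vl = {c: pl[i] for i, c in enumerate(comps)}
        vl["E"] = pl[-1]
        rs = {}
        for cname in list(comps) + ["E"]:
            key = f"r{cname}"
            rs[key] = fixed[key] if key in fixed else np.tanh(vals[key])
        s = 0.0
        if sib:
            s = fixed["s"] if "s" in fixed else float(np.tanh(vals["s"]))
        trait_vc = VarianceComponents(
            a2=vt.get("A", 0.0), d2=vt.get("D", 0.0), c2=vt.get("C", 0.0),
            e2=vt["E"], s=s if self.interaction_on in ("both", "trait") else 0.0)
        liab_vc = VarianceComponents(
            a2=vl.get("A", 0.0), d2=vl.get("D", 0.0), c2=vl.get("C", 0.0),
            e2=vl["E"],
            s=s if self.interaction_on in ("both", "liability") else 0.0)
        corr = EtiologicCorrelations(
            rA=rs.get("rA", 0.0), rC=rs.get("rC", 0.0),
            rD=rs.get("rD", 0.0), rE=rs["rE"])
        return trait_vc, liab_vc, corr, s, vals["tau_m"], vals["tau_f"]

    def _sigmas(self, trait_vc, liab_vc, corr):
        spec = BivariateTwinSpec(trait=trait_vc, liability=liab_vc, corr=corr,
                                 thresholds=ThresholdSet(0.0, 0.0))
        return (implied_moments(spec, "MZ"), implied_moments(spec, "DZ"))

    # -- fitting --------------------------------------------------------------

    def fit(self, table: PhenotypeTable, trait: str, diagnosis: str):
        df = table.df.copy()
        if self.standardize:
            df[trait] = standardize_by_sex(df[trait], df["sex"])
        work = PhenotypeTable(df=df, measures=[trait], diagnoses=[diagnosis])
        wide = work.to_pairs(trait, diagnosis)
        has_data = ~(wide[["t1", "t2", "y1", "y2"]].isna().all(axis=1))
        wide = wide[has_data]
        self.n_pairs_ = int(len(wide))
        groups = _build_groups(wide)

        y_all = pd.to_numeric(df[diagnosis]).to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau0 = estimate_thresholds(y_all, df["sex"].to_numpy())
        tau0_m = tau0.tau_m if np.isfinite(tau0.tau_m) else 3.5
        tau0_f = tau0.tau_f if np.isfinite(tau0.tau_f) else 3.5

        names = self._param_names()

        def negll(x):
            try:
                trait_vc, liab_vc, corr, s, tau_m, tau_f = self._unpack(x)
                sig_mz, sig_dz = self._sigmas(trait_vc, liab_vc, corr)
            except ValueError:
                return 1e12
            ll = _total_loglik(groups, sig_mz, sig_dz, tau_m, tau_f)
            if not np.isfinite(ll):
                return 1e12
            return -ll

        x0 = self._initial_point(names, wide, tau0_m, tau0_f)
        starts = [x0]
        rng = np.random.default_rng(0)
        for _ in range(self.n_restarts):
            jitter = rng.normal(0.0, 0.5, size=len(names))
            # keep threshold starts close to their moment estimates
            jitter[-2:] = rng.normal(0.0, 0.05, size=2)
            starts.append(x0 + jitter)

        best = None
        for start in starts:
            res = optimize.minimize(
                negll, start, method="L-BFGS-B",
                options={"maxiter": self.maxiter, "ftol": self.tol,
                         "gtol": 1e-8})
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        if not best.success and best.fun >= 1e12:
            raise RuntimeError(
                f"twin model optimization failed: {best.message}")
        self.converged_ = bool(best.success)
        if not best.success:
            logger.warning("twin model fit did not fully converge: %s",
                           best.message)

        self._finalize(best, names)
        return self

    def _initial_point(self, names, wide, tau0_m, tau0_f) -> np.ndarray:
        fam, sib = self._family()
        comps = _FAMILY_COMPONENTS[fam]
        k = len(comps)
        # crude moment-based variance-share starts from cross-twin Pearson r
        r_mz, _ = _double_entry_pearson(
            wide.loc[wide["zyg_class"] == "MZ", "t1"].to_numpy(),
            wide.loc[wide["zyg_class"] == "MZ", "t2"].to_numpy())
        r_dz, _ = _double_entry_pearson(
            wide.loc[wide["zyg_class"] == "DZ", "t1"].to_numpy(),
            wide.loc[wide["zyg_class"] == "DZ", "t2"].to_numpy())
        a2 = np.clip(2 * ((r_mz if np.isfinite(r_mz) else 0.4)
                          - (r_dz if np.isfinite(r_dz) else 0.2)), 0.05, 0.9)
        vals = {}
        if k:
            shares = {"A": a2, "C": 0.15, "D": 0.15}
            props = np.array([shares[c] for c in comps])
            scale = min(1.0, 0.9 / props.sum())
            props = props * scale
            raws = _raw_from_props(np.append(props, 1.0 - props.sum()))
            for i in range(k):
                vals[f"vt_{i}"] = raws[i]
                vals[f"vl_{i}"] = raws[i]
        for n in names:
            if n.startswith("r"):
                vals[n] = np.arctanh(0.3)
            elif n == "s":
                vals[n] = 0.0
        vals["tau_m"], vals["tau_f"] = tau0_m, tau0_f
        return np.array([vals[n] for n in names])

    def _finalize(self, res, names) -> None:
        trait_vc, liab_vc, corr, s, tau_m, tau_f = self._unpack(res.x)
        self.params_raw_ = dict(zip(names, res.x))
        self.trait_vc_ = trait_vc
        self.liability_vc_ = liab_vc
        self.corr_ = corr
        self.s_ = s
        self.thresholds_ = ThresholdSet(tau_m=float(tau_m), tau_f=float(tau_f))
        self.loglik_ = float(-res.fun)
        self.n_params_ = len(names)
        self.bic_ = float(-2.0 * self.loglik_
                          + self.n_params_ * np.log(max(self.n_pairs_, 1)))
        self.ra_ = float(self.corr_.rA)
        self.re_ = float(self.corr_.rE)
        t, l, c = trait_vc, liab_vc, corr
        gt = t.a2 + t.d2
        gl = l.a2 + l.d2
        if gt > 0 and gl > 0:
            self.rg_ = float((c.rA * np.sqrt(t.a2 * l.a2)
                              + c.rD * np.sqrt(t.d2 * l.d2))
                             / np.sqrt(gt * gl))
        else:
            self.rg_ = np.nan
        terms = {
            "A": c.rA * np.sqrt(t.a2 * l.a2),
            "C": c.rC * np.sqrt(t.c2 * l.c2),
            "D": c.rD * np.sqrt(t.d2 * l.d2),
            "E": c.rE * np.sqrt(t.e2 * l.e2),
        }
        self.rph_ = float(sum(terms.values()))
        if abs(self.rph_) > 1e-10:
            fam, _ = self._family()
            active = list(_FAMILY_COMPONENTS[fam]) + ["E"]
            self.shares_ = {k: float(terms[k] / self.rph_) for k in active}
        else:
            self.shares_ = {}
            logger.warning("phenotypic correlation ~0; shares undefined")
        self.boundary_flags_ = [
            name for name, v in (("a2_trait", t.a2), ("a2_liab", l.a2),
                                 ("c2_trait", t.c2), ("c2_liab", l.c2),
                                 ("d2_trait", t.d2), ("d2_liab", l.d2))
            if v > 1e-6 and (v < 1e-4 or v > 1 - 1e-4)
        ] + [name for name, v in (("rA", c.rA), ("rC", c.rC), ("rD", c.rD),
                                  ("rE", c.rE))
             if abs(v) > 1 - 1e-4]

    def to_frame(self) -> pd.DataFrame:
        """One row in the layout of a model-fit summary table."""
        t, l = self.trait_vc_, self.liability_vc_
        return pd.DataFrame([{
            "family": self.family if not self.sibling_interaction
            else f"{self.family}-s",
            "a2_trait": t.a2, "c2_trait": t.c2, "d2_trait": t.d2,
            "e2_trait": t.e2,
            "a2_liab": l.a2, "c2_liab": l.c2, "d2_liab": l.d2,
            "e2_liab": l.e2,
            "rA": self.ra_, "rG": self.rg_, "rE": self.re_, "s": self.s_,
            "rPh_implied": self.rph_,
            "genetic_share": (self.shares_.get("A", 0.0)
                              + self.shares_.get("D", 0.0))
            if self.shares_ else np.nan,
            "loglik": self.loglik_, "n_params": self.n_params_,
            "BIC": self.bic_, "n_pairs": self.n_pairs_,
        }])

    def profile_ci(self, table: PhenotypeTable, trait: str, diagnosis: str,
                   param: str = "rA", level: float = 0.95,
                   n_grid: int = 8) -> tuple[float, float]:
        """Profile-likelihood CI for one correlation parameter.

        Re-fits with ``param`` pinned over a grid and inverts the likelihood
        ratio at the chi-square(1) critical value by interpolation.
        """
        crit = chi2.isf(1 - level, df=1) / 2.0
        base_ll = self.loglik_
        center = {"rA": self.ra_, "rE": self.re_,
                  "rC": self.corr_.rC, "rD": self.corr_.rD}[param]

        def profile(v) -> float:
            m = BivariateTwinModel(
                family=self.family,
                sibling_interaction=self.sibling_interaction,
                interaction_on=self.interaction_on,
                fixed={**(self.fixed or {}), param: float(v)},
                standardize=self.standardize, n_restarts=0, tol=self.tol)
            m.fit(table, trait, diagnosis)
            return base_ll - m.loglik_

        bounds = []
        for direction in (-1.0, 1.0):
            lo, hi = center, center + direction
            hi = float(np.clip(hi, -0.999, 0.999))
            val = None
            grid = np.linspace(lo, hi, n_grid + 1)[1:]
            prev_v, prev_d = lo, 0.0
            for v in grid:
                d = profile(v)
                if d >= crit:
                    # linear interpolation in the deviance
                    frac = (crit - prev_d) / (d - prev_d)
                    val = prev_v + frac * (v - prev_v)
                    break
                prev_v, prev_d = v, d
            bounds.append(val if val is not None else direction * 1.0)
        return (float(min(bounds)), float(max(bounds)))


def fit_structural(table: PhenotypeTable, trait: str, diagnosis: str,
                   family: str = "AE", **kwargs) -> BivariateTwinModel:
    return BivariateTwinModel(family=family, **kwargs).fit(
        table, trait, diagnosis)


# ---------------------------------------------------------------------------
# model selection and decomposition
# ---------------------------------------------------------------------------

def lrt(full: BivariateTwinModel, reduced: BivariateTwinModel) -> dict:
    """Likelihood-ratio test of a nested reduction against the full model."""
    df = full.n_params_ - reduced.n_params_
    if df <= 0:
        raise ValueError("reduced model must have fewer free parameters")
    stat = 2.0 * (full.loglik_ - reduced.loglik_)
    # a tiny negative deviance is boundary-convergence slop, not non-nesting
    if stat < -1e-2:
        raise ValueError(
            "reduced model has higher log-likelihood; models are not nested"
        )
    stat = max(stat, 0.0)
    return {"chi2": float(stat), "df": int(df),
            "p": float(chi2.sf(stat, df))}


def select_model(full: BivariateTwinModel,
                 reduced: list[BivariateTwinModel] | None = None,
                 alpha: float = 0.05,
                 labels: list[str] | None = None) -> pd.DataFrame:
    """BIC table and LRT chain from the full model to its reductions.

    A reduction is favored when the likelihood-ratio test against the full
    model is non-significant at ``alpha``; among the admissible models the
    most parsimonious (fewest parameters, ties by lower BIC) is flagged.
    P-values at a boundary of the parameter space are reported from the
    plain chi-square reference (conservative for variance components).
    """
    reduced = reduced or []
    models = [full] + list(reduced)
    if labels is None:
        labels = [f"{m.family}{'-s' if m.sibling_interaction else ''}"
                  + (f" fixed={m.fixed}" if m.fixed else "")
                  for m in models]
    rows = []
    admissible = [(0, full)]
    for i, m in enumerate(models):
        row = {"model": labels[i], "loglik": m.loglik_,
               "n_params": m.n_params_, "BIC": m.bic_,
               "chi2": np.nan, "df": np.nan, "p": np.nan}
        if i > 0:
            t = lrt(full, m)
            row.update(t)
            if t["p"] >= alpha:
                admissible.append((i, m))
        rows.append(row)
    best_i = min(admissible,
                 key=lambda im: (im[1].n_params_, im[1].bic_))[0]
    out = pd.DataFrame(rows)
    out["favored"] = [i == best_i for i in range(len(models))]
    return out


def decompose_phenotypic_correlation(fit: BivariateTwinModel) -> dict:
    """Share of the phenotypic correlation from each active component.

    rPh = sum_k r_k sqrt(v_k,trait v_k,liability) over active components;
    each share is its term divided by rPh, so shares sum to 1 (the
    decomposition is on the latent phenotype scale, which coincides with
    the observed scale when the sibling-interaction path is zero).
    Undefined when rPh is ~0.
    """
    t, l, c = fit.trait_vc_, fit.liability_vc_, fit.corr_
    terms = {
        "A": c.rA * np.sqrt(t.a2 * l.a2),
        "C": c.rC * np.sqrt(t.c2 * l.c2),
        "D": c.rD * np.sqrt(t.d2 * l.d2),
        "E": c.rE * np.sqrt(t.e2 * l.e2),
    }
    rph = sum(terms.values())
    if abs(rph) <= 1e-10:
        raise ValueError("phenotypic correlation ~0; shares undefined")
    fam = fit.family.removesuffix("-s")
    active = list(_FAMILY_COMPONENTS[fam]) + ["E"]
    return {k: float(terms[k] / rph) for k in active}
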