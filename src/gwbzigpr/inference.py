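"""Hypothesis tests, diagnostics, and model-selection statistics.

Covers the full testing workflow around a (geographically weighted)
bivariate zero-inflated GP regression:

* variance test for over/underdispersion of each count margin,
* t test of the Pearson correlation between the two responses,
* variance-inflation factors for predictor multicollinearity,
* Glejser test for spatial heteroscedasticity of squared residuals,
* maximum-likelihood-ratio G² tests (joint, zero-state-only, Poisson-state-only),
* partial Wald Z tests and coefficient interpretation (rate / odds multipliers),
* corrected AIC and the model-similarity F ratio between global and local fits,
* grouping of locations by their sets of significant predictors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (
    BLOCKS,
    FitControl,
    FitResult,
    SpatialDataset,
    ThetaVector,
    bhhh_fit,
    fit_gwbzigpr,
    loglik,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "CoefficientReport",
    "variance_test",
    "correlation_test",
    "vif",
    "glejser_test",
    "mlrt_test",
    "wald_partial",
    "aicc",
    "model_similarity_f",
    "interpret_coefficients",
    "significance_groups",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | tuple | None
    critical_value: float | None
    p_value: float | None
    reject: bool | None
    alpha: float | None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "critical_value": self.critical_value,
            "p_value": self.p_value,
            "reject": self.reject,
            "alpha": self.alpha,
        }
        d.update(self.extra)
        return d


@dataclass
class CoefficientReport:
    """Per-parameter Wald summary; ``table`` has one row per (location,
    block, term)."""

    table: pd.DataFrame
    alpha: float

    def rendered(self) -> pd.DataFrame:
        out = self.table.copy()
        for col in ("estimate", "se", "z", "p_value", "exp_estimate"):
            out[col] = out[col].round(4 if col != "exp_estimate" else 3)
        return out


# ---------------------------------------------------------------------------
# dispersion / correlation / collinearity diagnostics
# ---------------------------------------------------------------------------

def variance_test(y: np.ndarray) -> TestResult:
    """Variance test ``VT = sum (y - ybar)^2 / ybar`` against the threshold 1.

    VT > 1 is read as overdispersion, VT < 1 underdispersion, VT = 1
    equidispersion.  The scale-free dispersion ratio ``VT/(n-1)`` (sample
    variance over mean) is reported alongside.
    """
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    if ybar <= 0:
        raise ValueError("variance test undefined: mean of y is not positive")
    vt = float(np.sum((y - ybar) ** 2) / ybar)
    label = "overdispersed" if vt > 1 else ("underdispersed" if vt < 1 else "equidispersed")
    return TestResult(name="variance_test", statistic=vt, df=None,
                      critical_value=1.0, p_value=None, reject=vt > 1, alpha=None,
                      extra={"classification": label,
                             "dispersion_ratio": vt / (len(y) - 1)})


def correlation_test(y1: np.ndarray, y2: np.ndarray, alpha: float = 0.05) -> TestResult:
    """t test of the Pearson correlation between the two count responses:
    ``t = r * sqrt(n-2) / sqrt(1-r^2)`` with ``n-2`` degrees of freedom."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = len(y1)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(y1) == 0 or np.std(y2) == 0:
        raise ValueError("correlation undefined for a constant response")
    r = float(np.corrcoef(y1, y2)[0, 1])
    if abs(r) >= 1.0:
        t = math.copysign(1e12, r)
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 2))
    return TestResult(name="correlation_test", statistic=t, df=n - 2,
                      critical_value=crit, p_value=p, reject=abs(t) > crit,
                      alpha=alpha, extra={"r": r})


def vif(X: np.ndarray) -> np.ndarray:
    """Variance-inflation factor per predictor column (no intercept in ``X``).

    Each predictor is regressed on the others plus an intercept;
    ``VIF = 1/(1-R^2)``, with ``inf`` for exact collinearity.
    """
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    if n <= q + 1:
        raise ValueError("need n > q+1 observations for VIF")
    out = np.empty(q)
    for j in range(q):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        yj = X[:, j]
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(np.sum((yj - yj.mean()) ** 2))
        rss = float(np.sum(resid**2))
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        out[j] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# heteroscedasticity (Glejser)
# ---------------------------------------------------------------------------

def glejser_test(fit: FitResult, dataset: SpatialDataset, alpha: float = 0.05,
                 j_slopes: int | None = None, df: int | None = None) -> TestResult:
    """Glejser-style test of spatial heteroscedasticity.

    The squared raw residuals of both responses (observed count minus fitted
    mean ``(1-p)*mu``) are regressed on the predictors as a two-equation
    multivariate linear model.  With ``S_full`` and ``S_0`` the residual
    covariance matrices of the full and intercept-only models,
    ``G = -[n - q - 1 - (j - q + 1)/2] * ln(|S_full| / |S_0|)`` is compared to
    a chi-square with ``2q`` degrees of freedom (``j`` defaults to the total
    slope count ``2q``).
    """
    theta = fit.theta if fit.kind == "global" else None
    if theta is None:
        raise ValueError("glejser_test expects a global fit")
    n, q = dataset.n, dataset.q
    resid = _raw_residuals(theta, dataset)
    E = resid**2
    Xf = dataset.X
    X0 = np.ones((n, 1))
    s_full = _resid_cov(Xf, E)
    s_null = _resid_cov(X0, E)
    det_f, det_0 = np.linalg.det(s_full), np.linalg.det(s_null)
    if det_f <= 0 or det_0 <= 0:
        raise np.linalg.LinAlgError("singular residual covariance in Glejser test")
    if j_slopes is None:
        j_slopes = 2 * q
    if df is None:
        df = 2 * q
    const = n - q - 1 - 0.5 * (j_slopes - q + 1)
    G = -const * math.log(det_f / det_0)
    crit = float(stats.chi2.ppf(1 - alpha, df))
    p = float(stats.chi2.sf(G, df))
    return TestResult(name="glejser_test", statistic=G, df=df, critical_value=crit,
                      p_value=p, reject=G > crit, alpha=alpha)


def _raw_residuals(theta: ThetaVector, dataset: SpatialDataset) -> np.ndarray:
    from scipy.special import expit

    mu1 = np.exp(np.clip(dataset.X @ theta.beta1, -30, 30))
    mu2 = np.exp(np.clip(dataset.X @ theta.beta2, -30, 30))
    p1 = expit(dataset.X @ theta.gamma1)
    p2 = expit(dataset.X @ theta.gamma2)
    return np.column_stack([dataset.y1 - (1 - p1) * mu1,
                            dataset.y2 - (1 - p2) * mu2])


def _resid_cov(X: np.ndarray, E: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, E, rcond=None)
    R = E - X @ coef
    return (R.T @ R) / len(E)


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

_BLOCK_SETS = {
    "both": ("gamma1", "gamma2", "beta1", "beta2"),
    "gamma": ("gamma1", "gamma2"),
    "beta": ("beta1", "beta2"),
}


def mlrt_test(full: FitResult, restricted_block: str, dataset: SpatialDataset,
              alpha: float = 0.05, df: int | None = None,
              control: FitControl = FitControl()) -> TestResult:
    """Maximum-likelihood-ratio test ``G² = 2(lnL_full - lnL_restricted)``.

    ``restricted_block`` is one of ``both`` (all slopes), ``gamma``
    (zero-state slopes), ``beta`` (Poisson-state slopes).  The restricted
    model refits the remaining parameters — intercepts, dispersions and the
    correlation factor stay free.  The default degrees of freedom equal the
    number of zeroed slope coefficients (multiplied by the number of
    locations for a geographically weighted fit).
    """
    if restricted_block not in _BLOCK_SETS:
        raise ValueError(f"restricted_block must be one of {sorted(_BLOCK_SETS)}")
    zero = _BLOCK_SETS[restricted_block]
    q = dataset.q
    if full.kind == "global":
        restricted = bhhh_fit(dataset, None, full.theta, control,
                              zero_slopes=zero, eta_fixed=full.eta_fixed,
                              eta_interval=full.eta_interval)
        ll_full, ll_restr = full.loglik, restricted.loglik
        if df is None:
            df = q * len(zero)
        if ll_full < ll_restr:
            # the restricted optimum dominates only through a poorly converged
            # full fit; refit the full model from the restricted solution
            refit = bhhh_fit(dataset, None, restricted.theta, control,
                             eta_fixed=full.eta_fixed,
                             eta_interval=full.eta_interval)
            ll_full = max(ll_full, refit.loglik)
    else:
        restricted = fit_gwbzigpr(dataset, full.weights.spec, control,
                                  zero_slopes=zero, eta_fixed=full.eta_fixed)
        ll_full, ll_restr = full.loglik, restricted.loglik
        if df is None:
            df = q * len(zero) * dataset.n
    g2 = 2.0 * (ll_full - ll_restr)
    if g2 < -1e-6:
        raise RuntimeError(
            f"negative G^2 = {g2:.3e}: the full fit did not converge; refit advised")
    g2 = max(g2, 0.0)
    crit = float(stats.chi2.ppf(1 - alpha, df))
    p = float(stats.chi2.sf(g2, df))
    return TestResult(name=f"mlrt_{restricted_block}", statistic=g2, df=df,
                      critical_value=crit, p_value=p, reject=g2 > crit, alpha=alpha,
                      extra={"loglik_full": ll_full, "loglik_restricted": ll_restr})


# ---------------------------------------------------------------------------
# Wald tests and interpretation
# ---------------------------------------------------------------------------

def _safe_exp(x: float) -> float:
    """exp() that reports inf instead of overflowing on an exploding
    (weakly identified) local estimate."""
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


def wald_partial(fit: FitResult, alpha: float = 0.05) -> CoefficientReport:
    """Partial Wald Z tests, ``Z = estimate/SE`` with two-sided normal
    p-values, for every estimated parameter (per location for a GW fit)."""
    labels = ThetaVector.labels(fit.q)
    rows = []
    for loc, (theta, se) in enumerate(zip(fit.thetas, fit.se)):
        est = theta.stack()
        ids = fit.dataset.ids[loc] if fit.kind == "gw" else "global"
        u, v = (fit.dataset.coords[loc] if fit.kind == "gw" else (np.nan, np.nan))
        for jdx, (block, term) in enumerate(labels):
            s = se[jdx]
            if not np.isfinite(s) or s == 0:
                z = p = np.nan
                unstable = True
            else:
                z = est[jdx] / s
                p = 2.0 * stats.norm.sf(abs(z))
                unstable = False
            rows.append({
                "location": ids, "u": u, "v": v, "block": block, "term": term,
                "estimate": est[jdx], "se": s, "z": z, "p_value": p,
                "exp_estimate": _safe_exp(est[jdx]) if block in BLOCKS else np.nan,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
                "unstable": unstable,
            })
    return CoefficientReport(table=pd.DataFrame(rows), alpha=alpha)


def interpret_coefficients(report: CoefficientReport) -> pd.DataFrame:
    """Multiplicative-effect table: ``exp(beta)`` as rate multipliers for the
    Poisson state, ``exp(gamma)`` as zero-odds multipliers for the zero state
    (rounded to 3 decimals in the rendered column)."""
    tab = report.table
    tab = tab[tab["block"].isin(BLOCKS)].copy()
    tab["state"] = np.where(tab["block"].str.startswith("beta"),
                            "poisson_state_rate_multiplier",
                            "zero_state_odds_multiplier")
    tab["multiplier"] = np.exp(tab["estimate"])
    tab["multiplier_rounded"] = tab["multiplier"].round(3)
    return tab[["location", "block", "term", "estimate", "state",
                "multiplier", "multiplier_rounded", "significant"]]


def significance_groups(gw_fit: FitResult, alpha: float = 0.05) -> dict:
    """Group locations by their exact set of significant predictors.

    Returns, per regression block, a list of groups sorted by size:
    ``{"terms": sorted tuple, "locations": [...]}`` — the groups partition
    the locations.
    """
    report = wald_partial(gw_fit, alpha)
    tab = report.table
    out: dict[str, list[dict]] = {}
    for block in BLOCKS:
        sub = tab[(tab["block"] == block) & (tab["term"] != "intercept")]
        groups: dict[tuple, list] = {}
        for loc, g in sub.groupby("location", sort=False):
            key = tuple(sorted(g.loc[g["significant"], "term"]))
            groups.setdefault(key, []).append(loc)
        out[block] = sorted(
            ({"terms": list(k), "locations": v} for k, v in groups.items()),
            key=lambda d: -len(d["locations"]))
    return out


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def aicc(loglik_value: float, r: int, n: int) -> float:
    """Corrected AIC: ``-2 lnL + 2r + 2r(r+1)/(n-r-1)``."""
    if n <= r + 1:
        raise ValueError(f"AICc undefined for n={n} <= r+1={r + 1}")
    return -2.0 * loglik_value + 2.0 * r + 2.0 * r * (r + 1.0) / (n - r - 1.0)


def model_similarity_f(dev_global: float, df_global: float,
                       dev_gw: float, df_gw: float,
                       alpha: float = 0.05) -> TestResult:
    """F ratio comparing per-degree-of-freedom deviance of the global and
    geographically weighted models:
    ``F = (dev_global/df_global) / (dev_gw/df_gw)``."""
    if min(dev_global, df_global, dev_gw, df_gw) <= 0:
        raise ValueError("deviances and degrees of freedom must be positive")
    F = (dev_global / df_global) / (dev_gw / df_gw)
    crit = float(stats.f.ppf(1 - alpha, df_global, df_gw))
    p = float(stats.f.sf(F, df_global, df_gw))
    return TestResult(name="model_similarity_f", statistic=F,
                      df=(df_global, df_gw), critical_value=crit, p_value=p,
                      reject=F > crit, alpha=alpha)
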