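"""Generalized Poisson, zero-inflated GP, and bivariate zero-inflated GP distributions.

The bivariate family couples two zero-inflated generalized Poisson (ZIGP)
margins through a multiplicative factor ``1 + eta*(exp(-y1)-g1)*(exp(-y2)-g2)``
applied to the count (non-structural-zero) component, where
``g_l = E[exp(-Y_l)]`` is the Laplace transform of the GP margin evaluated at 1.
Because the factor has zero expectation under the product measure, the joint
pmf is properly normalized for any admissible ``eta``.

Parameterization of the GP component: mean ``mu`` and dispersion ``phi >= 0``,
with variance ``mu*(1+phi*mu)**2``.  ``phi = 0`` recovers the Poisson
distribution.  Writing ``theta = mu/(1+phi*mu)`` and
``lam = phi*mu/(1+phi*mu)`` gives the classical Consul GP(theta, lam) with
``0 <= lam < 1``, which is always a proper distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "GpParams",
    "ZigpParams",
    "BivZigpParams",
    "CellIndicators",
    "DistributionError",
    "ConvergenceError",
    "InvalidEtaError",
    "gp_pmf",
    "gp_logpmf",
    "zigp_pmf",
    "solve_s",
    "laplace_g",
    "bzigp_joint_pmf",
    "bzigp_grid_pmf",
    "eta_bounds",
    "bzigp_sample",
    "support_cap",
]

HARD_SUPPORT_CEILING = 500
_SURVIVAL_TOL = 1e-12


class DistributionError(ValueError):
    """Invalid argument or parameter for a distribution."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class InvalidEtaError(DistributionError):
    """The multiplicative factor produced a negative probability."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GpParams:
    """Generalized Poisson parameters (mean ``mu``, dispersion ``phi``)."""

    mu: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise DistributionError(f"mu must be positive and finite, got {self.mu}")
        if not (self.phi >= 0 and math.isfinite(self.phi)):
            raise DistributionError(
                f"phi must be finite and >= 0 (underdispersion unsupported), got {self.phi}"
            )

    @property
    def theta(self) -> float:
        """Consul rate parameter ``mu/(1+phi*mu)``."""
        return self.mu / (1.0 + self.phi * self.mu)

    @property
    def lam(self) -> float:
        """Consul dispersion parameter ``phi*mu/(1+phi*mu)`` in [0, 1)."""
        return self.phi * self.mu / (1.0 + self.phi * self.mu)


@dataclass(frozen=True)
class ZigpParams:
    """Zero-inflated GP: GP component plus structural-zero probability ``p``."""

    gp: GpParams
    p: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p < 1.0):
            raise DistributionError(f"p must lie in [0, 1), got {self.p}")


@dataclass(frozen=True)
class BivZigpParams:
    """Two ZIGP margins coupled by the multiplicative factor ``eta``.

    ``g1, g2`` are the Laplace factors ``E[exp(-Y_l)]`` of the GP components,
    ``s1, s2`` the solutions of the implicit equation
    ``ln s = phi*mu*(s-1)/(1+phi*mu) - 1`` they derive from.  Use
    :meth:`build` to construct a consistent instance.
    """

    margin1: ZigpParams
    margin2: ZigpParams
    eta: float
    g1: float = field(default=float("nan"))
    g2: float = field(default=float("nan"))
    s1: float = field(default=float("nan"))
    s2: float = field(default=float("nan"))

    @classmethod
    def build(cls, margin1: ZigpParams, margin2: ZigpParams, eta: float) -> "BivZigpParams":
        s1 = solve_s(margin1.gp)
        s2 = solve_s(margin2.gp)
        g1 = laplace_g(margin1.gp, s=s1)
        g2 = laplace_g(margin2.gp, s=s2)
        return cls(margin1=margin1, margin2=margin2, eta=float(eta),
                   g1=g1, g2=g2, s1=s1, s2=s2)

    def __post_init__(self) -> None:
        if not math.isfinite(self.eta):
            raise DistributionError(f"eta must be finite, got {self.eta}")
        for label, s, gp in (("1", self.s1, self.margin1.gp), ("2", self.s2, self.margin2.gp)):
            if math.isnan(s):
                continue
            resid = abs(math.log(s) - (gp.lam * (s - 1.0) - 1.0))
            if resid > 1e-10:
                raise DistributionError(
                    f"s{label} inconsistent with its implicit equation (residual {resid:.2e})"
                )
        for label, g, s, gp in (("1", self.g1, self.s1, self.margin1.gp),
                                ("2", self.g2, self.s2, self.margin2.gp)):
            if math.isnan(g):
                continue
            if abs(g - math.exp(gp.theta * (s - 1.0))) > 1e-10:
                raise DistributionError(f"g{label} inconsistent with its defining equation")


@dataclass(frozen=True)
class CellIndicators:
    """Zero-pattern membership flags for paired count observations.

    ``b``, ``c``, ``d`` mark membership in the cells (y1=0, y2>0),
    (y1>0, y2=0) and (y1>0, y2>0); the remaining cell (0, 0) is implied by
    ``1 - b - c - d``.  ``n1..n4`` are the cell counts.
    """

    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    @classmethod
    def from_counts(cls, y1: np.ndarray, y2: np.ndarray) -> "CellIndicators":
        y1 = np.asarray(y1)
        y2 = np.asarray(y2)
        b = ((y1 == 0) & (y2 > 0)).astype(int)
        c = ((y1 > 0) & (y2 == 0)).astype(int)
        d = ((y1 > 0) & (y2 > 0)).astype(int)
        return cls(b=b, c=c, d=d)

    @property
    def a(self) -> np.ndarray:
        return 1 - self.b - self.c - self.d

    @property
    def n1(self) -> int:
        return int(self.a.sum())

    @property
    def n2(self) -> int:
        return int(self.b.sum())

    @property
    def n3(self) -> int:
        return int(self.c.sum())

    @property
    def n4(self) -> int:
        return int(self.d.sum())


# ---------------------------------------------------------------------------
# vectorized kernels (shared with the estimation module)
# ---------------------------------------------------------------------------

def _gp_logpmf_arr(y, theta, lam_over=None, phi=None, mu=None):
    """log GP pmf, array-valued.

    Accepts either (theta, phi) or (mu, phi); log pmf is
    ``y*log(theta) + (y-1)*log1p(phi*y) - gammaln(y+1) - theta*(1+phi*y)``.
    """
    y = np.asarray(y, dtype=float)
    if theta is None:
        theta = mu / (1.0 + phi * mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.maximum(theta, 1e-300)), 0.0)
    return term + (y - 1.0) * np.log1p(phi * y) - gammaln(y + 1.0) - theta * (1.0 + phi * y)


def solve_s_array(lam: np.ndarray, tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Vectorized fixed-point solve of ``ln s = lam*(s-1) - 1`` for ``lam in [0,1)``."""
    lam = np.asarray(lam, dtype=float)
    s = np.full(np.shape(lam), math.exp(-1.0))
    for _ in range(max_iter):
        s_new = np.exp(lam * (s - 1.0) - 1.0)
        if np.max(np.abs(s_new - s)) < tol:
            s = s_new
            break
        s = s_new
    return s


def bzigp_logpmf_arrays(y1, y2, mu1, mu2, p1, p2, phi1, phi2, eta):
    """Joint log pmf of the bivariate ZIGP, fully vectorized/broadcastable.

    All inputs broadcast together; returns ``-inf`` where the multiplicative
    factor drives the pmf non-positive (the caller decides whether that is an
    error or a rejected likelihood evaluation).
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    mu1, mu2 = np.asarray(mu1, float), np.asarray(mu2, float)
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    phi1 = np.asarray(phi1, float)
    phi2 = np.asarray(phi2, float)
    eta = np.asarray(eta, float)

    th1 = mu1 / (1.0 + phi1 * mu1)
    th2 = mu2 / (1.0 + phi2 * mu2)
    lam1 = phi1 * mu1 / (1.0 + phi1 * mu1)
    lam2 = phi2 * mu2 / (1.0 + phi2 * mu2)
    g1 = np.exp(th1 * (solve_s_array(lam1) - 1.0))
    g2 = np.exp(th2 * (solve_s_array(lam2) - 1.0))

    f01 = np.exp(-th1)            # GP P(Y=0)
    f02 = np.exp(-th2)
    t1 = np.exp(-y1) - g1
    t2 = np.exp(-y2) - g2

    lgp1 = _gp_logpmf_arr(y1, th1, phi=phi1)
    lgp2 = _gp_logpmf_arr(y2, th2, phi=phi2)

    with np.errstate(divide="ignore", invalid="ignore"):
        # (y1>0, y2>0)
        brack_d = 1.0 + eta * t1 * t2
        case_d = (np.log1p(-p1) + np.log1p(-p2) + lgp1 + lgp2
                  + np.log(np.where(brack_d > 0, brack_d, np.nan)))
        # (y1=0, y2>0)
        inner_b = p1 + (1.0 - p1) * f01 * (1.0 + eta * (1.0 - g1) * t2)
        case_b = (np.log1p(-p2) + lgp2
                  + np.log(np.where(inner_b > 0, inner_b, np.nan)))
        # (y1>0, y2=0)
        inner_c = p2 + (1.0 - p2) * f02 * (1.0 + eta * t1 * (1.0 - g2))
        case_c = (np.log1p(-p1) + lgp1
                  + np.log(np.where(inner_c > 0, inner_c, np.nan)))
        # (0, 0)
        inner_a = (p1 * p2
                   + p1 * (1.0 - p2) * f02
                   + p2 * (1.0 - p1) * f01
                   + (1.0 - p1) * (1.0 - p2) * f01 * f02
                   * (1.0 + eta * (1.0 - g1) * (1.0 - g2)))
        case_a = np.log(np.where(inner_a > 0, inner_a, np.nan))

    m1 = y1 > 0
    m2 = y2 > 0
    out = np.select(
        [m1 & m2, ~m1 & m2, m1 & ~m2],
        [case_d, case_b, case_c],
        default=case_a,
    )
    return np.where(np.isnan(out), -np.inf, out)


# ---------------------------------------------------------------------------
# scalar public API
# ---------------------------------------------------------------------------

def _check_count(y) -> int:
    if isinstance(y, (bool, np.bool_)):
        raise DistributionError(f"count must be an integer, got {y!r}")
    yi = np.asarray(y)
    if yi.shape != ():
        raise DistributionError("y must be a scalar")
    if not float(yi) == int(yi):
        raise DistributionError(f"count must be an integer, got {y!r}")
    if int(yi) < 0:
        raise DistributionError(f"count must be non-negative, got {y!r}")
    return int(yi)


def gp_logpmf(y: int, params: GpParams) -> float:
    """Log pmf of the generalized Poisson distribution."""
    yi = _check_count(y)
    return float(_gp_logpmf_arr(np.asarray(yi), params.theta, phi=params.phi))


def gp_pmf(y: int, params: GpParams) -> float:
    """Pmf of the generalized Poisson distribution.

    Computed in log space and exponentiated; at ``phi=0`` this is exactly the
    Poisson pmf with mean ``mu``.
    """
    return float(np.exp(gp_logpmf(y, params)))


def zigp_pmf(y: int, params: ZigpParams) -> float:
    """Pmf of the zero-inflated GP: mixture of a point mass at zero and a GP."""
    yi = _check_count(y)
    base = gp_pmf(yi, params.gp)
    if yi == 0:
        return params.p + (1.0 - params.p) * base
    return (1.0 - params.p) * base


def solve_s(params: GpParams, tol: float = 1e-12, max_iter: int = 200) -> float:
    """Solve the implicit equation ``ln s = phi*mu*(s-1)/(1+phi*mu) - 1``.

    Fixed-point iteration ``s <- exp(lam*(s-1) - 1)`` from ``s = exp(-1)``;
    the map is a contraction for ``lam in [0,1)``.  Falls back to bisection if
    the residual stalls; raises :class:`ConvergenceError` on failure.
    """
    lam = params.lam
    s = math.exp(-1.0)
    for _ in range(max_iter):
        s_new = math.exp(lam * (s - 1.0) - 1.0)
        if abs(s_new - s) < tol:
            s = s_new
            break
        s = s_new
    resid = abs(math.log(s) - (lam * (s - 1.0) - 1.0))
    if resid > 1e-10:
        # bisection fallback on F(s) = ln s - lam*(s-1) + 1, increasing near root
        from scipy.optimize import brentq

        try:
            s = brentq(lambda x: math.log(x) - lam * (x - 1.0) + 1.0, 1e-12, 1.0,
                       xtol=1e-14)
        except Exception as exc:  # pragma: no cover - defensive
            raise ConvergenceError(
                f"solve_s failed to converge (last residual {resid:.3e})"
            ) from exc
        resid = abs(math.log(s) - (lam * (s - 1.0) - 1.0))
        if resid > 1e-10:
            raise ConvergenceError(
                f"solve_s failed to converge (last residual {resid:.3e})"
            )
    return s


def laplace_g(params: GpParams, s: float | None = None) -> float:
    """Laplace factor ``g = E[exp(-Y)] = exp(mu*(s-1)/(1+phi*mu))`` of the GP."""
    if s is None:
        s = solve_s(params)
    return math.exp(params.theta * (s - 1.0))


def bzigp_joint_pmf(y1: int, y2: int, params: BivZigpParams) -> float:
    """Joint pmf of the bivariate ZIGP at ``(y1, y2)``.

    Dispatches on the zero pattern to the four case formulas; at ``eta = 0``
    it factorizes exactly into the product of the marginal ZIGP pmfs.
    Raises :class:`InvalidEtaError` if the multiplicative factor makes the
    pmf negative at the queried point.
    """
    y1i = _check_count(y1)
    y2i = _check_count(y2)
    lp = bzigp_logpmf_arrays(
        y1i, y2i,
        params.margin1.gp.mu, params.margin2.gp.mu,
        params.margin1.p, params.margin2.p,
        params.margin1.gp.phi, params.margin2.gp.phi,
        params.eta,
    )
    val = float(np.exp(lp))
    if not np.isfinite(lp) and _factor_negative(y1i, y2i, params):
        raise InvalidEtaError(
            f"eta={params.eta} yields a negative pmf at (y1={y1i}, y2={y2i})"
        )
    return val


def _factor_negative(y1: int, y2: int, params: BivZigpParams) -> bool:
    t1 = math.exp(-y1) - params.g1 if y1 > 0 else 1.0 - params.g1
    t2 = math.exp(-y2) - params.g2 if y2 > 0 else 1.0 - params.g2
    if y1 > 0 and y2 > 0:
        return 1.0 + params.eta * t1 * t2 < 0
    # for zero cells the bracket is mixed with positive mass; only flag clear violations
    return 1.0 + params.eta * t1 * t2 < 0


def support_cap(params: GpParams, tol: float = _SURVIVAL_TOL,
                ceiling: int = HARD_SUPPORT_CEILING) -> int:
    """Smallest ``y`` with GP survival mass below ``tol`` (hard ceiling 500)."""
    y = np.arange(ceiling + 1)
    pmf = np.exp(_gp_logpmf_arr(y, params.theta, phi=params.phi))
    surv = 1.0 - np.cumsum(pmf)
    below = np.nonzero(surv < tol)[0]
    return int(below[0]) if below.size else ceiling


def eta_bounds(margin1: ZigpParams, margin2: ZigpParams,
               support_cap_: int | None = None) -> tuple[float, float]:
    """Largest interval of ``eta`` keeping the joint pmf non-negative.

    Computed from the extreme values of ``exp(-y) - g`` on the truncated
    support grid of each margin.
    """
    caps = (support_cap(margin1.gp), support_cap(margin2.gp))
    if support_cap_ is not None:
        caps = (support_cap_, support_cap_)
    bounds_t = []
    for margin, cap in zip((margin1, margin2), caps):
        g = laplace_g(margin.gp)
        t = np.exp(-np.arange(cap + 1)) - g
        bounds_t.append((t.min(), t.max()))
    prods = [a * b for a in bounds_t[0] for b in bounds_t[1]]
    m_min, m_max = min(prods), max(prods)
    eta_max = math.inf if m_min >= 0 else -1.0 / m_min
    eta_min = -math.inf if m_max <= 0 else -1.0 / m_max
    return (eta_min, eta_max)


def bzigp_grid_pmf(params: BivZigpParams,
                   cap1: int | None = None, cap2: int | None = None) -> np.ndarray:
    """Joint pmf evaluated on the truncated grid ``[0..cap1] x [0..cap2]``.

    Raises :class:`InvalidEtaError` if any grid value is negative.
    """
    if cap1 is None:
        cap1 = support_cap(params.margin1.gp)
    if cap2 is None:
        cap2 = support_cap(params.margin2.gp)
    y1 = np.arange(cap1 + 1)[:, None]
    y2 = np.arange(cap2 + 1)[None, :]
    lp = bzigp_logpmf_arrays(
        y1, y2,
        params.margin1.gp.mu, params.margin2.gp.mu,
        params.margin1.p, params.margin2.p,
        params.margin1.gp.phi, params.margin2.gp.phi,
        params.eta,
    )
    bad = ~np.isfinite(lp)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise InvalidEtaError(
            f"eta={params.eta} yields a negative pmf at (y1={int(i)}, y2={int(j)})"
        )
    return np.exp(lp)


def bzigp_sample(params: BivZigpParams, n: int,
                 seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` iid pairs by inverse-CDF sampling on the truncated grid.

    The grid is enumerated row-major (y1 outer, y2 inner) and the truncation
    remainder (at most ~1e-10) is folded back by renormalization, so a fixed
    seed fully determines the output.  Returns an ``(n, 2)`` integer array.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = bzigp_grid_pmf(params)
    flat = grid.ravel(order="C")
    total = flat.sum()
    if total < 1.0 - 1e-6:  # pragma: no cover - defensive
        logger.warning("truncated grid mass %.12f is unexpectedly low", total)
    cdf = np.cumsum(flat / total)
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="right")
    idx = np.minimum(idx, flat.size - 1)
    n2 = grid.shape[1]
    return np.column_stack([idx // n2, idx % n2]).astype(np.int64)
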