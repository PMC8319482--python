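"""Maximum-likelihood estimation of bivariate zero-inflated GP regression,
globally (BZIGPR) and geographically weighted (GWBZIGPR).

Each margin ``l`` links its mean and structural-zero probability to the
predictors through ``mu_l = exp(x' beta_l)`` and ``p_l = logistic(x' gamma_l)``;
the two margins share the dispersion parameters ``phi_1, phi_2`` and the
multiplicative correlation factor ``eta``.  The (kernel-weighted)
log-likelihood is maximized by BHHH iteration: the Hessian is approximated by
the negative outer product of per-observation score vectors, and the scores
themselves are central finite differences of each observation's weighted
log-density (the analytic derivatives of this model are unwieldy and buy
nothing at the problem sizes targeted here).

Internally ``phi`` is optimized on the log scale and ``eta`` on a scaled
logit over its admissibility interval, so the BHHH update is unconstrained;
estimates and standard errors are reported on the natural scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
import scipy.optimize
from scipy.special import expit, logit

from .distributions import (
    CellIndicators,
    bzigp_logpmf_arrays,
    laplace_g,
    solve_s_array,
)
from .spatial_weights import WeightMatrix, kernel_weights, distance_matrix, KernelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialDataset",
    "ThetaVector",
    "FitControl",
    "FitResult",
    "EstimationError",
    "local_params",
    "loglik",
    "score_per_obs",
    "bhhh_fit",
    "init_univariate",
    "fit_bzigpr",
    "fit_gwbzigpr",
    "dataset_eta_bounds",
]

_LINPRED_CLIP = 30.0
BLOCKS = ("gamma1", "gamma2", "beta1", "beta2")


class EstimationError(RuntimeError):
    """Estimation failed (singular Hessian, inadmissible start, ...)."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialDataset:
    """One row per location: id, planar coordinates, two counts, design matrix.

    ``X`` is ``n x (q+1)`` with a leading intercept column of ones.
    """

    ids: np.ndarray
    coords: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", np.asarray(self.ids))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "y1", np.asarray(self.y1, dtype=np.int64))
        object.__setattr__(self, "y2", np.asarray(self.y2, dtype=np.int64))
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        n = len(self.ids)
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n, 2)")
        if self.y1.shape != (n,) or self.y2.shape != (n,):
            raise ValueError("responses must be length-n vectors")
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise ValueError("X must have one row per location")
        if np.any(self.y1 < 0) or np.any(self.y2 < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.coords))):
            raise ValueError("X and coords must be finite")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def q(self) -> int:
        return self.X.shape[1] - 1

    @cached_property
    def cells(self) -> CellIndicators:
        return CellIndicators.from_counts(self.y1, self.y2)


@dataclass(frozen=True)
class ThetaVector:
    """Full parameter set: regression blocks, dispersions, correlation factor.

    Natural-scale stacking order: ``[gamma1, gamma2, beta1, beta2, phi1,
    phi2, eta]`` with each regression block of length ``q+1``.
    """

    gamma1: np.ndarray
    gamma2: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    phi1: float
    phi2: float
    eta: float

    def __post_init__(self) -> None:
        for name in BLOCKS:
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.phi1 < 0 or self.phi2 < 0:
            raise ValueError("phi must be non-negative")
        arrs = [getattr(self, b) for b in BLOCKS] + [[self.phi1, self.phi2, self.eta]]
        if not all(np.all(np.isfinite(a)) for a in arrs):
            raise ValueError("theta must be finite")

    @property
    def q(self) -> int:
        return len(self.beta1) - 1

    @property
    def dim(self) -> int:
        return 4 * (self.q + 1) + 3

    def stack(self) -> np.ndarray:
        return np.concatenate([self.gamma1, self.gamma2, self.beta1, self.beta2,
                               [self.phi1, self.phi2, self.eta]])

    @classmethod
    def from_stack(cls, vec: np.ndarray, q: int) -> "ThetaVector":
        vec = np.asarray(vec, dtype=float)
        k = q + 1
        return cls(gamma1=vec[:k], gamma2=vec[k:2 * k], beta1=vec[2 * k:3 * k],
                   beta2=vec[3 * k:4 * k], phi1=float(vec[4 * k]),
                   phi2=float(vec[4 * k + 1]), eta=float(vec[4 * k + 2]))

    @staticmethod
    def labels(q: int) -> list[tuple[str, str]]:
        """(block, term) labels matching the stacked order."""
        terms = ["intercept"] + [f"x{j}" for j in range(1, q + 1)]
        out = [(b, t) for b in BLOCKS for t in terms]
        out += [("phi1", "phi1"), ("phi2", "phi2"), ("eta", "eta")]
        return out


@dataclass(frozen=True)
class FitControl:
    eps: float = 1e-6
    max_iter: int = 200
    max_halvings: int = 20


@dataclass
class FitResult:
    """Fitted model: one parameter set (global) or one per location (GW)."""

    kind: str                       # "global" or "gw"
    thetas: list[ThetaVector]
    se: list[np.ndarray]            # natural-scale SEs, stacked order, NaN if fixed
    loglik: float
    n_iter: np.ndarray
    converged: np.ndarray
    dataset: SpatialDataset
    eta_interval: tuple[float, float]
    zero_slopes: tuple[str, ...] = ()
    eta_fixed: float | None = None
    weights: WeightMatrix | None = None
    local_logliks: np.ndarray | None = None
    trace: list[float] | None = None

    @property
    def theta(self) -> ThetaVector:
        if self.kind != "global":
            raise ValueError("use .thetas for a geographically weighted fit")
        return self.thetas[0]

    @property
    def q(self) -> int:
        return self.dataset.q

    @property
    def n_params(self) -> int:
        """Number of freely estimated parameters in one theta vector."""
        dim = self.thetas[0].dim
        dim -= (self.q) * len(self.zero_slopes)
        if self.eta_fixed is not None:
            dim -= 1
        return dim

    @property
    def deviance(self) -> float:
        """-2 log-likelihood (the deviance convention used throughout)."""
        return -2.0 * self.loglik

    def all_converged(self) -> bool:
        return bool(np.all(self.converged))


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def _linpreds(theta_rows: np.ndarray, X: np.ndarray, q: int, warn: list | None = None):
    """Per-observation (mu, p) for a batch of stacked natural parameter rows."""
    k = q + 1
    g1 = theta_rows[:, :k]
    g2 = theta_rows[:, k:2 * k]
    b1 = theta_rows[:, 2 * k:3 * k]
    b2 = theta_rows[:, 3 * k:4 * k]
    eb1 = X @ b1.T
    eb2 = X @ b2.T
    if warn is not None and not warn and (np.abs(eb1).max(initial=0) > _LINPRED_CLIP
                                          or np.abs(eb2).max(initial=0) > _LINPRED_CLIP):
        logger.debug("linear predictor clipped at +/-%.0f", _LINPRED_CLIP)
        warn.append(True)
    mu1 = np.exp(np.clip(eb1, -_LINPRED_CLIP, _LINPRED_CLIP)).T
    mu2 = np.exp(np.clip(eb2, -_LINPRED_CLIP, _LINPRED_CLIP)).T
    p1 = expit(X @ g1.T).T
    p2 = expit(X @ g2.T).T
    return mu1, mu2, p1, p2


def _logdens_natural(theta_rows: np.ndarray, dataset: SpatialDataset,
                     warn: list | None = None) -> np.ndarray:
    """Per-observation log joint density for a (m, dim) batch of natural thetas."""
    theta_rows = np.atleast_2d(theta_rows)
    q = dataset.q
    k = q + 1
    mu1, mu2, p1, p2 = _linpreds(theta_rows, dataset.X, q, warn)
    phi1 = np.maximum(theta_rows[:, 4 * k], 0.0)[:, None]
    phi2 = np.maximum(theta_rows[:, 4 * k + 1], 0.0)[:, None]
    eta = theta_rows[:, 4 * k + 2][:, None]
    bad_phi = (theta_rows[:, 4 * k] < 0) | (theta_rows[:, 4 * k + 1] < 0)
    ld = bzigp_logpmf_arrays(dataset.y1[None, :], dataset.y2[None, :],
                             mu1, mu2, p1, p2, phi1, phi2, eta)
    ld[bad_phi] = -np.inf
    return ld


def local_params(theta: ThetaVector, x_row: np.ndarray):
    """One observation's bivariate ZIGP parameters implied by ``theta``."""
    from .distributions import BivZigpParams, GpParams, ZigpParams

    x_row = np.asarray(x_row, dtype=float)
    mu1 = float(np.exp(np.clip(x_row @ theta.beta1, -_LINPRED_CLIP, _LINPRED_CLIP)))
    mu2 = float(np.exp(np.clip(x_row @ theta.beta2, -_LINPRED_CLIP, _LINPRED_CLIP)))
    p1 = float(expit(x_row @ theta.gamma1))
    p2 = float(expit(x_row @ theta.gamma2))
    m1 = ZigpParams(GpParams(mu1, theta.phi1), p1)
    m2 = ZigpParams(GpParams(mu2, theta.phi2), p2)
    return BivZigpParams.build(m1, m2, theta.eta)


def loglik(theta: ThetaVector, dataset: SpatialDataset,
           weights: np.ndarray | None = None) -> float:
    """Kernel-weighted log-likelihood ``sum_i w_i * ln f(y1i, y2i | theta, x_i)``.

    Returns ``-inf`` (and logs the offending observation) if any weighted
    contribution is non-finite.
    """
    ld = _logdens_natural(theta.stack()[None, :], dataset)[0]
    if weights is None:
        weights = np.ones(dataset.n)
    contrib = np.where(weights > 0, ld * weights, 0.0)
    if not np.all(np.isfinite(contrib)):
        bad = int(np.nonzero(~np.isfinite(contrib))[0][0])
        logger.debug("non-finite log-likelihood contribution at observation %d", bad)
        return -math.inf
    return float(contrib.sum())


def _fd_scores(f_batch, x: np.ndarray, n_obs: int,
               rel_step: float = 1e-5, lower_bounds=None) -> np.ndarray:
    """Central finite-difference per-observation scores of a batched
    log-density function ``f_batch((m, dim)) -> (m, n_obs)``.

    Step ``rel_step * max(1, |x_j|)`` per coordinate; coordinates with a lower
    bound fall back to a forward difference at the boundary.  Non-finite
    perturbations shrink the step by 10, three times, before erroring.
    """
    dim = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    scores = np.empty((n_obs, dim))
    pending = np.arange(dim)
    for attempt in range(4):
        plus = np.repeat(x[None, :], pending.size, axis=0)
        minus = plus.copy()
        plus[np.arange(pending.size), pending] += h[pending]
        minus[np.arange(pending.size), pending] -= h[pending]
        forward = np.zeros(pending.size, dtype=bool)
        if lower_bounds is not None:
            for r, j in enumerate(pending):
                lb = lower_bounds[j]
                if lb is not None and x[j] - h[j] < lb:
                    minus[r] = x
                    forward[r] = True
        fp = f_batch(plus)
        fm = f_batch(minus)
        denom = np.where(forward, h[pending], 2.0 * h[pending])
        vals = (fp - fm) / denom[:, None]
        ok = np.all(np.isfinite(vals), axis=1)
        scores[:, pending[ok]] = vals[ok].T
        pending = pending[~ok]
        if pending.size == 0:
            return scores
        if attempt < 3:
            h[pending] /= 10.0
    raise EstimationError(
        f"non-finite finite-difference perturbation for coordinates {pending.tolist()}")


def score_per_obs(theta: ThetaVector, dataset: SpatialDataset,
                  weights: np.ndarray | None = None) -> np.ndarray:
    """Per-observation score vectors (natural scale), as central finite
    differences of each observation's weighted log-density."""
    if weights is None:
        weights = np.ones(dataset.n)
    x = theta.stack()
    lb = [None] * x.size
    lb[4 * (theta.q + 1)] = 0.0
    lb[4 * (theta.q + 1) + 1] = 0.0

    def f_batch(rows):
        return _logdens_natural(rows, dataset) * weights[None, :]

    if not math.isfinite(loglik(theta, dataset, weights)):
        raise EstimationError("log-likelihood is not finite at theta")
    return _fd_scores(f_batch, x, dataset.n, lower_bounds=lb)


# ---------------------------------------------------------------------------
# free-scale transform
# ---------------------------------------------------------------------------

_PHI_FLOOR = 1e-8


@dataclass(frozen=True)
class _FreeMap:
    """Bijection between ThetaVector and the unconstrained BHHH coordinates.

    ``phi -> log(phi)``; ``eta -> logit((eta - lo)/(hi - lo))`` over a frozen
    admissibility interval; regression blocks untouched.  ``fixed`` marks
    coordinates excluded from optimization (held at their value in the base
    vector).
    """

    q: int
    eta_lo: float
    eta_hi: float
    fixed: np.ndarray  # bool over the stacked layout

    @property
    def k(self) -> int:
        return self.q + 1

    def to_free(self, theta: ThetaVector) -> np.ndarray:
        v = theta.stack()
        v[4 * self.k] = math.log(max(theta.phi1, _PHI_FLOOR))
        v[4 * self.k + 1] = math.log(max(theta.phi2, _PHI_FLOOR))
        u = (theta.eta - self.eta_lo) / (self.eta_hi - self.eta_lo)
        v[4 * self.k + 2] = logit(min(max(u, 1e-12), 1 - 1e-12))
        return v

    def to_natural_rows(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(rows).copy()
        rows[:, 4 * self.k] = np.exp(np.clip(rows[:, 4 * self.k], -50.0, 50.0))
        rows[:, 4 * self.k + 1] = np.exp(np.clip(rows[:, 4 * self.k + 1], -50.0, 50.0))
        rows[:, 4 * self.k + 2] = (self.eta_lo + (self.eta_hi - self.eta_lo)
                                   * expit(rows[:, 4 * self.k + 2]))
        return rows

    def from_free(self, vec: np.ndarray) -> ThetaVector:
        return ThetaVector.from_stack(self.to_natural_rows(vec)[0], self.q)

    def jacobian_diag(self, vec: np.ndarray) -> np.ndarray:
        """d(natural)/d(free) at a free-scale point, for delta-method SEs."""
        j = np.ones(vec.size)
        j[4 * self.k] = math.exp(vec[4 * self.k])
        j[4 * self.k + 1] = math.exp(vec[4 * self.k + 1])
        u = expit(vec[4 * self.k + 2])
        j[4 * self.k + 2] = (self.eta_hi - self.eta_lo) * u * (1 - u)
        return j


def _zero_slope_mask(q: int, zero_slopes: tuple[str, ...],
                     eta_fixed: bool) -> np.ndarray:
    k = q + 1
    fixed = np.zeros(4 * k + 3, dtype=bool)
    for bi, name in enumerate(BLOCKS):
        if name in zero_slopes:
            fixed[bi * k + 1: (bi + 1) * k] = True
    if eta_fixed:
        fixed[4 * k + 2] = True
    return fixed


def dataset_eta_bounds(theta: ThetaVector, dataset: SpatialDataset,
                       pad: float = 0.999) -> tuple[float, float]:
    """Admissible ``eta`` interval across all observations at ``theta``.

    Uses the extreme values of ``exp(-y) - g_l`` per margin and observation
    (``y = 0`` and the large-count limit); the intersection over observations
    is shrunk slightly (``pad``) so the logit transform never sits exactly on
    the boundary.
    """
    mu1, mu2, _, _ = _linpreds(theta.stack()[None, :], dataset.X, theta.q)
    lam1 = theta.phi1 * mu1[0] / (1 + theta.phi1 * mu1[0])
    lam2 = theta.phi2 * mu2[0] / (1 + theta.phi2 * mu2[0])
    th1 = mu1[0] / (1 + theta.phi1 * mu1[0])
    th2 = mu2[0] / (1 + theta.phi2 * mu2[0])
    g1 = np.exp(th1 * (solve_s_array(lam1) - 1.0))
    g2 = np.exp(th2 * (solve_s_array(lam2) - 1.0))
    # per-observation extreme products of (exp(-y)-g) factors
    t1_lo, t1_hi = -g1, 1.0 - g1
    t2_lo, t2_hi = -g2, 1.0 - g2
    prods = np.stack([t1_lo * t2_lo, t1_lo * t2_hi, t1_hi * t2_lo, t1_hi * t2_hi])
    m_min = prods.min(axis=0)
    m_max = prods.max(axis=0)
    eta_hi = float(np.min(-1.0 / m_min[m_min < 0])) if np.any(m_min < 0) else math.inf
    eta_lo = float(np.max(-1.0 / m_max[m_max > 0])) if np.any(m_max > 0) else -math.inf
    if not math.isfinite(eta_hi):
        eta_hi = 1e6
    if not math.isfinite(eta_lo):
        eta_lo = -1e6
    return (pad * eta_lo, pad * eta_hi)


# ---------------------------------------------------------------------------
# BHHH core
# ---------------------------------------------------------------------------

def bhhh_core(f_batch, x0: np.ndarray, n_obs: int,
              control: FitControl = FitControl()):
    """Generic BHHH maximizer over a batched per-observation log-density.

    ``f_batch((m, dim)) -> (m, n_obs)`` returns weighted per-observation log
    densities for a batch of parameter rows.  Update:
    ``x <- x + (sum_i g_i g_i')^{-1} sum_i g_i`` with step halving to enforce
    a non-decreasing objective.  Returns ``(x, ll, scores, n_iter, converged,
    trace)``.
    """
    x = np.asarray(x0, dtype=float).copy()
    ll = float(f_batch(x[None, :]).sum())
    if not math.isfinite(ll):
        raise EstimationError("objective not finite at the starting value")
    trace = [ll]
    converged = False
    stalled = False
    n_iter = 0
    stall_tol = 1e-8
    for n_iter in range(1, control.max_iter + 1):
        scores = _fd_scores(f_batch, x, n_obs)
        g = scores.sum(axis=0)
        H = scores.T @ scores
        step = _solve_opg(H, g)
        # step halving: accept the first non-decreasing candidate
        t = 1.0
        accepted = False
        for _ in range(control.max_halvings + 1):
            cand = x + t * step
            ll_new = float(f_batch(cand[None, :]).sum())
            if math.isfinite(ll_new) and ll_new >= ll:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            stalled = True
            break
        delta = float(np.max(np.abs(cand - x)))
        improvement = ll_new - ll
        if improvement < stall_tol * (1.0 + abs(ll)):
            # the outer-product direction only crawls from here on; do not
            # commit a sub-noise move, hand over to the quasi-Newton polish
            stalled = True
            break
        x, ll = cand, ll_new
        trace.append(ll)
        if delta <= control.eps:
            converged = True
            break
    if not converged:
        x, ll, polished = _polish_bfgs(f_batch, x, ll)
        if polished:
            trace.append(ll)
        converged = stalled or polished
    scores = _fd_scores(f_batch, x, n_obs)
    return x, ll, scores, n_iter, converged, trace


def _polish_bfgs(f_batch, x: np.ndarray, ll: float,
                 rel_step: float = 1e-5) -> tuple[np.ndarray, float, bool]:
    """Quasi-Newton refinement of a stalled BHHH iterate.

    The outer-product update converges only linearly near the optimum, so the
    last digits of the log-likelihood are finished with BFGS on the summed
    objective, with central-difference gradients batched through ``f_batch``.
    The result is kept only if it strictly improves the objective.
    """
    dim = x.size
    idx = np.arange(dim)

    def negf_and_grad(z):
        h = rel_step * np.maximum(1.0, np.abs(z))
        for _ in range(4):
            pts = np.repeat(z[None, :], 2 * dim + 1, axis=0)
            pts[1 + idx, idx] += h
            pts[1 + dim + idx, idx] -= h
            vals = f_batch(pts).sum(axis=1)
            if np.all(np.isfinite(vals)):
                grad = (vals[1:1 + dim] - vals[1 + dim:]) / (2.0 * h)
                return -vals[0], -grad
            if not math.isfinite(vals[0]):
                return math.inf, np.zeros(dim)
            h = h / 10.0
        return math.inf, np.zeros(dim)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.optimize.minimize(
            negf_and_grad, x, jac=True, method="BFGS",
            options={"gtol": 1e-5, "maxiter": 100})
    if math.isfinite(res.fun) and -res.fun > ll:
        return np.asarray(res.x, dtype=float), float(-res.fun), True
    return x, ll, False


def _solve_opg(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    ridge = 0.0
    for attempt in range(4):
        try:
            A = H + ridge * np.eye(H.shape[0]) if ridge else H
            step = np.linalg.solve(A, g)
            if np.all(np.isfinite(step)):
                return step
        except np.linalg.LinAlgError:
            pass
        ridge = 1e-8 * 10.0**attempt
    raise EstimationError("singular BHHH Hessian (outer-product of scores)")


def _opg_se(scores: np.ndarray) -> np.ndarray:
    """SEs from the inverse outer-product-of-gradients matrix.

    A parameter whose score column (numerically) vanishes — e.g. the
    correlation factor pinned at its admissibility bound — makes the OPG
    singular; the pseudo-inverse then still yields finite SEs for the
    identified directions, with the degenerate one flagged as NaN.
    """
    H = scores.T @ scores
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        if np.all(np.isfinite(se)):
            return se
    except np.linalg.LinAlgError:
        pass
    scale = np.sqrt(np.clip(np.diag(H), 1e-300, None))
    Hs = H / scale[:, None] / scale[None, :]
    cov = np.linalg.pinv(Hs, rcond=1e-10, hermitian=True)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None)) / scale
    dead = np.diag(H) <= 1e-300
    se[dead] = np.nan
    return se


# ---------------------------------------------------------------------------
# univariate initialization
# ---------------------------------------------------------------------------

def _zigp_logdens_rows(rows: np.ndarray, y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(m, 2k+1) univariate free rows [gamma, beta, log phi] -> (m, n)."""
    k = X.shape[1]
    p = expit(X @ rows[:, :k].T).T
    mu = np.exp(np.clip(X @ rows[:, k:2 * k].T, -_LINPRED_CLIP, _LINPRED_CLIP)).T
    phi = np.exp(np.clip(rows[:, 2 * k], -50.0, 50.0))[:, None]
    th = mu / (1.0 + phi * mu)
    ylog = y[None, :].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lgp = (np.where(ylog > 0, ylog * np.log(np.maximum(th, 1e-300)), 0.0)
               + (ylog - 1.0) * np.log1p(phi * ylog)
               - _gammaln_cached(y)[None, :] - th * (1.0 + phi * ylog))
        zero_val = np.log(p + (1.0 - p) * np.exp(-th))
        out = np.where(y[None, :] == 0, zero_val, np.log1p(-p) + lgp)
    return out


def _gammaln_cached(y: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(y.astype(float) + 1.0)


def _crude_margin_init(y: np.ndarray, k: int):
    beta = np.zeros(k)
    beta[0] = math.log(float(np.mean(y)) + 0.5)
    gamma = np.zeros(k)
    gamma[0] = -1.0
    return gamma, beta, 0.1


def _fit_univariate_zigp(y: np.ndarray, X: np.ndarray, control: FitControl):
    """Univariate ZIGPR fit by the same BHHH machinery (unit weights)."""
    import statsmodels.api as sm

    k = X.shape[1]
    try:
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        beta0 = np.asarray(glm.params, dtype=float)
        mu_hat = np.exp(np.clip(X @ beta0, -_LINPRED_CLIP, _LINPRED_CLIP))
        f0 = float(np.mean(np.exp(-mu_hat)))
        p0 = min(max((np.mean(y == 0) - f0) / max(1.0 - f0, 1e-6), 0.02), 0.9)
    except Exception:
        gamma, beta0, phi0 = _crude_margin_init(y, k)
        p0 = float(expit(gamma[0]))
    gamma0 = np.zeros(k)
    gamma0[0] = float(logit(p0))
    x0 = np.concatenate([gamma0, beta0, [math.log(0.1)]])

    def f_batch(rows):
        return _zigp_logdens_rows(rows, y, X)

    x, ll, _, _, conv = bhhh_core(f_batch, x0, len(y), control)[:5]
    return x[:k], x[k:2 * k], math.exp(x[2 * k]), ll, conv


def init_univariate(dataset: SpatialDataset,
                    control: FitControl = FitControl()) -> ThetaVector:
    """Starting values from separate univariate ZIGPR fits of each margin.

    ``eta`` always starts at 0.  A failed marginal fit falls back to crude
    moment-based values with a warning.
    """
    parts = []
    for label, y in (("y1", dataset.y1), ("y2", dataset.y2)):
        try:
            gamma, beta, phi, _, _ = _fit_univariate_zigp(y, dataset.X, control)
            if not (np.all(np.isfinite(gamma)) and np.all(np.isfinite(beta))):
                raise EstimationError("non-finite marginal estimate")
        except Exception as exc:
            logger.warning("marginal ZIGPR fit for %s failed (%s); using fallback",
                           label, exc)
            gamma, beta, phi = _crude_margin_init(y, dataset.X.shape[1])
            gamma[0] = 0.0
        parts.append((gamma, beta, phi))
    (g1, b1, phi1), (g2, b2, phi2) = parts
    return ThetaVector(gamma1=g1, gamma2=g2, beta1=b1, beta2=b2,
                       phi1=phi1, phi2=phi2, eta=0.0)


# ---------------------------------------------------------------------------
# global and geographically weighted fits
# ---------------------------------------------------------------------------

def _make_bivariate_batch(dataset: SpatialDataset, weights: np.ndarray,
                          freemap: _FreeMap, base_free: np.ndarray,
                          active: np.ndarray):
    keep = weights > 0
    y1 = dataset.y1[keep]
    y2 = dataset.y2[keep]
    X = dataset.X[keep]
    w = weights[keep]
    q = freemap.q
    k = q + 1
    warn: list = []

    def f_batch(sub_rows: np.ndarray) -> np.ndarray:
        sub_rows = np.atleast_2d(sub_rows)
        rows = np.repeat(base_free[None, :], sub_rows.shape[0], axis=0)
        rows[:, active] = sub_rows
        nat = freemap.to_natural_rows(rows)
        mu1, mu2, p1, p2 = _linpreds(nat, X, q, warn)
        ld = bzigp_logpmf_arrays(y1[None, :], y2[None, :], mu1, mu2, p1, p2,
                                 nat[:, 4 * k][:, None], nat[:, 4 * k + 1][:, None],
                                 nat[:, 4 * k + 2][:, None])
        return ld * w[None, :]

    return f_batch, int(keep.sum())


def bhhh_fit(dataset: SpatialDataset, weights: np.ndarray | None,
             theta0: ThetaVector, control: FitControl = FitControl(),
             zero_slopes: tuple[str, ...] = (), eta_fixed: float | None = None,
             eta_interval: tuple[float, float] | None = None) -> FitResult:
    """One BHHH maximization of the (weighted) bivariate log-likelihood.

    ``zero_slopes`` freezes the slope coefficients of the named blocks at 0
    (intercepts stay free) — used by the likelihood-ratio tests; ``eta_fixed``
    freezes the correlation factor.
    """
    if weights is None:
        weights = np.ones(dataset.n)
    weights = np.asarray(weights, dtype=float)
    q = dataset.q
    if eta_interval is None:
        eta_interval = dataset_eta_bounds(theta0, dataset)
    fixed = _zero_slope_mask(q, zero_slopes, eta_fixed is not None)
    freemap = _FreeMap(q=q, eta_lo=eta_interval[0], eta_hi=eta_interval[1],
                       fixed=fixed)
    base_theta = theta0
    if zero_slopes or eta_fixed is not None:
        kw = {}
        for name in zero_slopes:
            blk = getattr(theta0, name).copy()
            blk[1:] = 0.0
            kw[name] = blk
        if eta_fixed is not None:
            kw["eta"] = eta_fixed
        base_theta = replace(theta0, **kw)
    base_free = freemap.to_free(base_theta)
    active = np.nonzero(~fixed)[0]
    f_batch, n_eff = _make_bivariate_batch(dataset, weights, freemap,
                                           base_free, active)
    if n_eff < active.size:
        raise EstimationError(
            f"only {n_eff} positively weighted observations for {active.size} "
            "free parameters; increase the bandwidth")
    x, ll, scores, n_iter, conv, trace = bhhh_core(f_batch, base_free[active],
                                                   n_eff, control)
    full_free = base_free.copy()
    full_free[active] = x
    theta_hat = freemap.from_free(full_free)
    if eta_fixed is not None:
        # the logit round trip leaves float dust on the frozen value
        theta_hat = replace(theta_hat, eta=eta_fixed)
    se = np.full(base_free.size, np.nan)
    se_free = _opg_se(scores)
    se[active] = se_free * freemap.jacobian_diag(full_free)[active]
    return FitResult(kind="global", thetas=[theta_hat], se=[se], loglik=ll,
                     n_iter=np.array([n_iter]), converged=np.array([conv]),
                     dataset=dataset, eta_interval=eta_interval,
                     zero_slopes=tuple(zero_slopes), eta_fixed=eta_fixed,
                     trace=trace)


def fit_bzigpr(dataset: SpatialDataset, control: FitControl = FitControl(),
               theta0: ThetaVector | None = None,
               zero_slopes: tuple[str, ...] = (),
               eta_fixed: float | None = None) -> FitResult:
    """Global bivariate ZIGP regression (all kernel weights equal to 1)."""
    if theta0 is None:
        theta0 = init_univariate(dataset, control)
    return bhhh_fit(dataset, None, theta0, control,
                    zero_slopes=zero_slopes, eta_fixed=eta_fixed)


def fit_gwbzigpr(dataset: SpatialDataset, kernel_spec: KernelSpec,
                 control: FitControl = FitControl(),
                 global_fit: FitResult | None = None,
                 zero_slopes: tuple[str, ...] = (),
                 eta_fixed: float | None = None) -> FitResult:
    """Geographically weighted fit: one BHHH maximization per location.

    Each location maximizes the kernel-weighted log-likelihood, warm-started
    from the global estimate; all parameters (including ``phi`` and ``eta``)
    are refit locally.  The result's ``loglik`` is the sum over locations of
    each observation's log density at its own local estimate.
    """
    if global_fit is None or global_fit.zero_slopes != tuple(zero_slopes) \
            or global_fit.eta_fixed != eta_fixed:
        warm = fit_bzigpr(dataset, control, zero_slopes=zero_slopes,
                          eta_fixed=eta_fixed)
    else:
        warm = global_fit
    dmat = distance_matrix(dataset.coords)
    wm = kernel_weights(dmat, kernel_spec)
    thetas, ses, iters, convs, local_ll = [], [], [], [], []
    for i in range(dataset.n):
        w = wm.values[i]
        try:
            res = bhhh_fit(dataset, w, warm.theta, control,
                           zero_slopes=zero_slopes, eta_fixed=eta_fixed,
                           eta_interval=warm.eta_interval)
        except EstimationError as exc:
            raise EstimationError(
                f"local fit failed at location {dataset.ids[i]!r}: {exc}") from exc
        thetas.append(res.theta)
        ses.append(res.se[0])
        iters.append(res.n_iter[0])
        convs.append(res.converged[0])
        local_ll.append(res.loglik)
    # pointwise log-likelihood: each observation at its own local estimate
    point_ll = 0.0
    for i, th in enumerate(thetas):
        sub = SpatialDataset(ids=dataset.ids[i:i + 1], coords=dataset.coords[i:i + 1],
                             y1=dataset.y1[i:i + 1], y2=dataset.y2[i:i + 1],
                             X=dataset.X[i:i + 1])
        point_ll += loglik(th, sub)
    return FitResult(kind="gw", thetas=thetas, se=ses, loglik=point_ll,
                     n_iter=np.array(iters), converged=np.array(convs),
                     dataset=dataset, eta_interval=warm.eta_interval,
                     zero_slopes=tuple(zero_slopes), eta_fixed=eta_fixed,
                     weights=wm, local_logliks=np.array(local_ll))
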