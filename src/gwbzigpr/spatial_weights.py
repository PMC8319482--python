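"""Spatial kernel weights and GCV bandwidth selection for geographically
weighted fitting.

Four kernel families are supported: fixed/adaptive Gaussian and bisquare.
Fixed kernels use one global bandwidth ``h`` (a distance); adaptive kernels
use a neighbor count ``k`` and set each location's bandwidth to the distance
to its k-th nearest neighbor.  Coordinates are treated as planar — project
longitude/latitude before use.

Bandwidths are chosen by minimizing a generalized cross-validation (GCV)
score of a locally weighted linear smoother, summed over the two count
responses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "KERNEL_FAMILIES",
    "KernelSpec",
    "WeightMatrix",
    "BandwidthSearchResult",
    "SingularFitError",
    "distance_matrix",
    "kernel_weights",
    "gcv_score",
    "select_bandwidth",
]

KERNEL_FAMILIES = (
    "fixed_gaussian",
    "fixed_bisquare",
    "adaptive_gaussian",
    "adaptive_bisquare",
)

_ADAPTIVE_INFLATION = 1.0 + 1e-9  # keep the k-th neighbour's bisquare weight positive


class SingularFitError(np.linalg.LinAlgError):
    """A local weighted least-squares design was rank deficient."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its bandwidth (global ``h`` or neighbour count ``k``)."""

    family: str
    bandwidth: float

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; "
                             f"expected one of {KERNEL_FAMILIES}")
        if self.adaptive:
            if self.bandwidth != int(self.bandwidth) or self.bandwidth < 1:
                raise ValueError(
                    f"adaptive kernels need an integer neighbour count k >= 1, "
                    f"got {self.bandwidth}")
        elif not self.bandwidth > 0:
            raise ValueError(f"bandwidth must be positive, got {self.bandwidth}")

    @property
    def adaptive(self) -> bool:
        return self.family.startswith("adaptive")

    @property
    def gaussian(self) -> bool:
        return self.family.endswith("gaussian")


@dataclass(frozen=True)
class WeightMatrix:
    """Kernel weights: ``values[i, j]`` weights observation ``j`` in the local
    fit at location ``i``."""

    values: np.ndarray
    distances: np.ndarray
    bandwidths: np.ndarray
    spec: KernelSpec


@dataclass
class BandwidthSearchResult:
    spec: KernelSpec
    gcv: float
    trace_v1: float
    trace: list[tuple[float, float]] = field(default_factory=list)


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix of planar coordinates (``n x 2``)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise ValueError("coords must be an (n, 2) array with n >= 2")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    d = cdist(coords, coords)
    off = d[~np.eye(len(d), dtype=bool)]
    if np.any(off == 0):
        logger.warning("duplicate coordinates detected (zero off-diagonal distance)")
    return d


def _per_location_bandwidths(distances: np.ndarray, spec: KernelSpec) -> np.ndarray:
    n = distances.shape[0]
    if spec.adaptive:
        k = int(spec.bandwidth)
        if not 1 <= k < n:
            raise ValueError(f"neighbour count k={k} out of range [1, {n - 1}]")
        # k-th order statistic among the other locations (self excluded)
        srt = np.sort(distances, axis=1)
        return srt[:, k] * _ADAPTIVE_INFLATION
    return np.full(n, float(spec.bandwidth))


def kernel_weights(distances: np.ndarray, spec: KernelSpec) -> WeightMatrix:
    """Evaluate the kernel on a distance matrix.

    Gaussian: ``exp(-0.5*(d/h)^2)``; bisquare: ``(1-(d/h)^2)^2`` for
    ``d <= h`` and 0 beyond.
    """
    distances = np.asarray(distances, dtype=float)
    h = _per_location_bandwidths(distances, spec)
    ratio = distances / h[:, None]
    if spec.gaussian:
        w = np.exp(-0.5 * ratio**2)
    else:
        w = np.where(ratio <= 1.0, (1.0 - ratio**2) ** 2, 0.0)
    return WeightMatrix(values=w, distances=distances, bandwidths=h, spec=spec)


def gcv_score(X: np.ndarray, y: np.ndarray, coords: np.ndarray,
              spec: KernelSpec,
              distances: np.ndarray | None = None) -> tuple[float, float]:
    """GCV of the locally weighted linear smoother implied by ``spec``.

    The smoother row at location ``i`` is ``x_i' (X'W_i X)^{-1} X'W_i`` with
    ``W_i`` the diagonal kernel weights; ``GCV = n * RSS / (n - v1)^2`` where
    ``v1`` is the trace of the smoother.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if distances is None:
        distances = distance_matrix(coords)
    wm = kernel_weights(distances, spec)
    n, p = X.shape
    yhat = np.empty(n)
    v1 = 0.0
    for i in range(n):
        w = wm.values[i]
        Xw = X * w[:, None]
        A = X.T @ Xw
        try:
            c = np.linalg.solve(A, Xw.T @ y)
            si = np.linalg.solve(A, Xw.T[:, i])
        except np.linalg.LinAlgError as exc:
            raise SingularFitError(
                f"singular local weighted design at location {i} "
                f"(bandwidth {wm.bandwidths[i]:.6g})") from exc
        if np.linalg.matrix_rank(A) < p:
            raise SingularFitError(f"rank-deficient local design at location {i}")
        yhat[i] = X[i] @ c
        v1 += X[i] @ si
    rss = float(np.sum((y - yhat) ** 2))
    return n * rss / (n - v1) ** 2, float(v1)


def _objective(dataset, family: str, distances: np.ndarray):
    X, coords = dataset.X, dataset.coords
    responses = (dataset.y1.astype(float), dataset.y2.astype(float))

    def f(bw: float) -> tuple[float, float]:
        spec = KernelSpec(family, bw)
        total, v1 = 0.0, 0.0
        for y in responses:
            g, v = gcv_score(X, y, coords, spec, distances=distances)
            total += g
            v1 = v  # same smoother for both responses
        return total, v1

    return f


def _golden_section(f, lo: float, hi: float, tol: float,
                    trace: list[tuple[float, float]]):
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    trace.extend([(c, fc), (d, fd)])
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
            trace.append((c, fc))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
            trace.append((d, fd))
    return (c, fc) if fc < fd else (d, fd)


def select_bandwidth(dataset, family: str) -> BandwidthSearchResult:
    """Pick the bandwidth minimizing the two-response GCV sum.

    Fixed families: golden-section search on ``h`` over [smallest positive
    distance, largest distance].  Adaptive families: exhaustive scan of
    ``k in [q+2, n-1]``.
    """
    if family not in KERNEL_FAMILIES:
        raise ValueError(f"unknown kernel family {family!r}")
    distances = distance_matrix(dataset.coords)
    obj = _objective(dataset, family, distances)
    trace: list[tuple[float, float]] = []
    q = dataset.X.shape[1] - 1
    n = len(dataset.y1)

    def safe(bw: float) -> float:
        try:
            return obj(bw)[0]
        except SingularFitError:
            return math.inf

    if family.startswith("fixed"):
        off = distances[~np.eye(n, dtype=bool)]
        pos = off[off > 0]
        lo, hi = float(pos.min()), float(distances.max())
        best_bw, best_gcv = _golden_section(safe, lo, hi, 1e-3 * (hi - lo), trace)
    else:
        ks = range(q + 2, n)
        results = [(float(k), safe(float(k))) for k in ks]
        trace.extend(results)
        best_bw, best_gcv = min(results, key=lambda t: t[1])
        best_bw = float(int(best_bw))
    if not math.isfinite(best_gcv):
        raise SingularFitError(
            "all candidate bandwidths gave singular local fits; "
            "widen the search lower bound or check the design")
    gcv, v1 = obj(best_bw)
    return BandwidthSearchResult(spec=KernelSpec(family, best_bw), gcv=gcv,
                                 trace_v1=v1, trace=trace)
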