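"""Likelihood evaluation, scores, and BHHH fitting (global and local)."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gwbzigpr.distributions import (
    BivZigpParams,
    GpParams,
    ZigpParams,
    bzigp_joint_pmf,
)
from gwbzigpr.estimation import (
    FitControl,
    SpatialDataset,
    ThetaVector,
    _FreeMap,
    dataset_eta_bounds,
    fit_bzigpr,
    fit_gwbzigpr,
    init_univariate,
    loglik,
    score_per_obs,
)
from gwbzigpr.spatial_weights import KernelSpec
from gwbzigpr.synthetic import SimulationDesign, generate_dataset

SETTINGS = settings(derandomize=True, max_examples=30, deadline=None)


def _theta(q=2, seed=0):
    rng = np.random.default_rng(seed)
    k = q + 1
    return ThetaVector(gamma1=0.3 * rng.standard_normal(k),
                       gamma2=0.3 * rng.standard_normal(k),
                       beta1=0.25 * rng.standard_normal(k),
                       beta2=0.25 * rng.standard_normal(k),
                       phi1=0.2, phi2=0.3, eta=0.4)


def test_loglik_matches_pointwise_joint_pmf(small_dataset):
    dataset, _ = small_dataset
    theta = _theta()
    from scipy.special import expit

    total = 0.0
    for i in range(dataset.n):
        mu1 = math.exp(float(dataset.X[i] @ theta.beta1))
        mu2 = math.exp(float(dataset.X[i] @ theta.beta2))
        p1 = float(expit(dataset.X[i] @ theta.gamma1))
        p2 = float(expit(dataset.X[i] @ theta.gamma2))
        params = BivZigpParams.build(
            ZigpParams(GpParams(mu1, theta.phi1), p1),
            ZigpParams(GpParams(mu2, theta.phi2), p2), theta.eta)
        total += math.log(bzigp_joint_pmf(int(dataset.y1[i]),
                                          int(dataset.y2[i]), params))
    assert loglik(theta, dataset) == pytest.approx(total, abs=1e-8)


def test_scores_sum_to_the_loglik_gradient(small_dataset):
    dataset, _ = small_dataset
    rng = np.random.default_rng(2)
    weights = rng.uniform(0.2, 1.0, dataset.n)
    theta = _theta(seed=3)
    scores = score_per_obs(theta, dataset, weights)
    total = scores.sum(axis=0)
    x0 = theta.stack()
    # independent finite difference of the assembled objective
    for j in range(x0.size):
        h = 2e-6 * max(1.0, abs(x0[j]))
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        fp = loglik(ThetaVector.from_stack(xp, dataset.q), dataset, weights)
        fm = loglik(ThetaVector.from_stack(xm, dataset.q), dataset, weights)
        fd = (fp - fm) / (2 * h)
        assert total[j] == pytest.approx(fd, rel=2e-4, abs=2e-4)


def test_weighted_loglik_is_linear_in_the_weights(small_dataset):
    dataset, _ = small_dataset
    theta = _theta(seed=5)
    rng = np.random.default_rng(6)
    w1 = rng.uniform(0.1, 1.0, dataset.n)
    w2 = rng.uniform(0.1, 1.0, dataset.n)
    assert loglik(theta, dataset, w1 + w2) == pytest.approx(
        loglik(theta, dataset, w1) + loglik(theta, dataset, w2), abs=1e-8)


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

def test_global_fit_converges_and_beats_the_truth(small_dataset, small_global_fit):
    dataset, truths = small_dataset
    fit = small_global_fit
    assert fit.all_converged()
    assert fit.loglik >= loglik(truths[0], dataset)
    lo, hi = fit.eta_interval
    assert lo <= fit.theta.eta <= hi
    assert fit.theta.phi1 >= 0 and fit.theta.phi2 >= 0


def test_fit_is_deterministic(small_dataset, small_global_fit):
    dataset, _ = small_dataset
    again = fit_bzigpr(dataset)
    assert again.loglik == small_global_fit.loglik
    assert np.array_equal(again.theta.stack(), small_global_fit.theta.stack())


def test_warm_start_from_the_optimum_does_not_move(small_dataset, small_global_fit):
    # same frozen eta admissibility interval, as the local fits use it
    from gwbzigpr.estimation import bhhh_fit

    dataset, _ = small_dataset
    refit = bhhh_fit(dataset, None, small_global_fit.theta,
                     eta_interval=small_global_fit.eta_interval)
    assert abs(refit.loglik - small_global_fit.loglik) <= 1e-6
    assert np.max(np.abs(refit.theta.stack()
                         - small_global_fit.theta.stack())) <= 1e-5


def test_restricted_fit_zeroes_slopes_and_never_beats_the_full_fit(
        small_dataset, small_global_fit):
    dataset, _ = small_dataset
    restricted = fit_bzigpr(dataset, zero_slopes=("beta1", "beta2"))
    assert np.all(restricted.theta.beta1[1:] == 0)
    assert np.all(restricted.theta.beta2[1:] == 0)
    assert restricted.loglik <= small_global_fit.loglik + 1e-8


def test_eta_fixed_fit_freezes_the_correlation_factor(small_dataset):
    dataset, _ = small_dataset
    fit = fit_bzigpr(dataset, eta_fixed=0.0)
    assert fit.theta.eta == 0.0
    assert not np.isfinite(fit.se[0][-1])  # frozen parameter has no SE


def test_standard_errors_are_positive_for_free_parameters(medium_global_fit):
    # the correlation factor may pin at its admissibility bound, in which
    # case its score column vanishes and the SE is flagged as NaN
    se = medium_global_fit.se[0]
    coef = se[:-1]
    assert np.all(np.isfinite(coef))
    assert np.all(coef > 0)


def test_eta_interval_comes_from_the_dataset(small_dataset):
    dataset, _ = small_dataset
    theta0 = init_univariate(dataset)
    lo, hi = dataset_eta_bounds(theta0, dataset)
    assert lo < 0 < hi


# ---------------------------------------------------------------------------
# geographically weighted fit
# ---------------------------------------------------------------------------

def test_unit_weights_collapse_to_the_global_fit(small_dataset, small_global_fit):
    dataset, _ = small_dataset
    # an effectively flat gaussian kernel gives weight 1 everywhere
    gw = fit_gwbzigpr(dataset, KernelSpec("fixed_gaussian", 1e9),
                      global_fit=small_global_fit)
    for theta in gw.thetas:
        assert np.max(np.abs(theta.stack()
                             - small_global_fit.theta.stack())) <= 1e-6
        assert abs(loglik(theta, dataset)
                   - small_global_fit.loglik) <= 1e-6


def test_local_fits_adapt_and_fit_no_worse_pointwise(small_dataset,
                                                     small_global_fit):
    dataset, _ = small_dataset
    gw = fit_gwbzigpr(dataset, KernelSpec("fixed_bisquare", 1.2),
                      global_fit=small_global_fit)
    assert gw.kind == "gw"
    assert len(gw.thetas) == dataset.n
    assert np.all(gw.converged)
    # each local weighted objective at the local optimum dominates the
    # global parameter evaluated under the same weights
    for i in range(0, dataset.n, 8):
        w = gw.weights.values[i]
        assert loglik(gw.thetas[i], dataset, w) >= \
            loglik(small_global_fit.theta, dataset, w) - 1e-8


def test_too_narrow_kernel_names_the_failing_location(small_dataset):
    dataset, _ = small_dataset
    from gwbzigpr.estimation import EstimationError

    with pytest.raises(EstimationError, match="location"):
        fit_gwbzigpr(dataset, KernelSpec("fixed_bisquare", 0.15))


# ---------------------------------------------------------------------------
# parameter plumbing
# ---------------------------------------------------------------------------

@SETTINGS
@given(seed=st.integers(0, 10_000))
def test_theta_stack_roundtrip(seed):
    theta = _theta(q=3, seed=seed)
    back = ThetaVector.from_stack(theta.stack(), 3)
    assert np.array_equal(back.stack(), theta.stack())


def test_free_scale_transform_roundtrip():
    q = 2
    fm = _FreeMap(q=q, eta_lo=-2.0, eta_hi=1.5,
                  fixed=np.zeros(4 * (q + 1) + 3, dtype=bool))
    theta = _theta(q=q, seed=9)
    back = fm.from_free(fm.to_free(theta))
    assert np.max(np.abs(back.stack() - theta.stack())) < 1e-9


def test_theta_labels_match_stack_order():
    labels = ThetaVector.labels(2)
    assert len(labels) == 4 * 3 + 3
    assert labels[0] == ("gamma1", "intercept")
    assert labels[-1] == ("eta", "eta")


def test_dataset_validates_shapes():
    with pytest.raises(Exception):
        SpatialDataset(ids=np.arange(3), coords=np.zeros((3, 2)),
                       y1=np.zeros(2, dtype=int), y2=np.zeros(3, dtype=int),
                       X=np.ones((3, 2)))
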