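"""Diagnostics, likelihood-ratio and Wald tests, and model selection."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from gwbzigpr.inference import (
    aicc,
    correlation_test,
    glejser_test,
    interpret_coefficients,
    mlrt_test,
    model_similarity_f,
    significance_groups,
    variance_test,
    vif,
    wald_partial,
)
from gwbzigpr.estimation import fit_gwbzigpr
from gwbzigpr.spatial_weights import KernelSpec
from gwbzigpr.synthetic import (
    CoefficientSurface,
    SimulationDesign,
    generate_dataset,
)


# ---------------------------------------------------------------------------
# dispersion / correlation / collinearity
# ---------------------------------------------------------------------------

def test_variance_test_statistic_is_sum_of_squares_over_mean():
    y = np.array([0, 0, 1, 3, 6])
    ybar = y.mean()
    expect = float(np.sum((y - ybar) ** 2) / ybar)
    res = variance_test(y)
    assert res.statistic == pytest.approx(expect)
    assert res.extra["classification"] == "overdispersed"
    assert res.extra["dispersion_ratio"] == pytest.approx(expect / (len(y) - 1))


def test_variance_test_rejects_nonpositive_mean():
    with pytest.raises(ValueError):
        variance_test(np.zeros(5))


def test_correlation_test_matches_pearson_reference():
    rng = np.random.default_rng(1)
    y1 = rng.poisson(2.0, 80)
    y2 = y1 + rng.poisson(1.0, 80)
    res = correlation_test(y1, y2)
    r_ref, p_ref = stats.pearsonr(y1, y2)
    assert res.extra["r"] == pytest.approx(r_ref, abs=1e-12)
    assert res.p_value == pytest.approx(p_ref, rel=1e-6)
    assert res.reject == (abs(res.statistic) > res.critical_value)


def test_correlation_test_requires_variation():
    with pytest.raises(ValueError):
        correlation_test(np.ones(10), np.arange(10))


def test_vif_matches_statsmodels_reference():
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    rng = np.random.default_rng(3)
    X = rng.standard_normal((60, 3))
    X[:, 2] = 0.8 * X[:, 0] + 0.3 * rng.standard_normal(60)
    ours = vif(X)
    Xc = np.column_stack([np.ones(60), X])
    ref = [variance_inflation_factor(Xc, j) for j in range(1, 4)]
    assert np.allclose(ours, ref, rtol=1e-8)


# ---------------------------------------------------------------------------
# heteroscedasticity
# ---------------------------------------------------------------------------

def test_glejser_detects_strong_spatial_heterogeneity():
    # coefficients varying sharply in space inflate residual heterogeneity
    q = 2
    def vec(i0, s1):
        v = np.zeros(q + 1)
        v[0], v[1] = i0, s1
        return v
    design = SimulationDesign(
        n=150, q=q, seed=21,
        beta1=CoefficientSurface("two_cluster", vec(0.1, 0.2), vec(1.6, 0.0)),
        beta2=CoefficientSurface("two_cluster", vec(0.1, 0.2), vec(1.6, 0.0)))
    dataset, _ = generate_dataset(design)
    from gwbzigpr.estimation import fit_bzigpr

    fit = fit_bzigpr(dataset)
    res = glejser_test(fit, dataset)
    assert res.df == 2 * q
    assert res.statistic > 0
    assert res.critical_value == pytest.approx(
        stats.chi2.ppf(0.95, 2 * q), rel=1e-10)


def test_glejser_requires_a_global_fit(small_dataset, small_global_fit):
    dataset, _ = small_dataset
    gw = fit_gwbzigpr(dataset, KernelSpec("fixed_gaussian", 1e9),
                      global_fit=small_global_fit)
    with pytest.raises(ValueError):
        glejser_test(gw, dataset)


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

def test_mlrt_is_nonnegative_with_expected_df(medium_dataset, medium_global_fit):
    dataset, _ = medium_dataset
    res = mlrt_test(medium_global_fit, "beta", dataset)
    assert res.statistic >= 0
    assert res.df == 2 * dataset.q
    assert res.extra["loglik_full"] >= res.extra["loglik_restricted"] - 1e-8


def test_mlrt_joint_dominates_single_blocks(medium_dataset, medium_global_fit):
    dataset, _ = medium_dataset
    g_both = mlrt_test(medium_global_fit, "both", dataset).statistic
    g_beta = mlrt_test(medium_global_fit, "beta", dataset).statistic
    g_gamma = mlrt_test(medium_global_fit, "gamma", dataset).statistic
    assert g_both >= g_beta - 1e-6
    assert g_both >= g_gamma - 1e-6


def test_mlrt_detects_active_poisson_state_slopes():
    from gwbzigpr.estimation import fit_bzigpr

    def vec(i0, slopes):
        v = np.zeros(3)
        v[0], v[1:] = i0, slopes
        return v

    design = SimulationDesign(
        n=150, q=2, seed=31,
        beta1=CoefficientSurface("constant", vec(0.4, [0.6, -0.5])),
        beta2=CoefficientSurface("constant", vec(0.3, [-0.6, 0.5])))
    dataset, _ = generate_dataset(design)
    res = mlrt_test(fit_bzigpr(dataset), "beta", dataset)
    assert res.reject


def test_mlrt_rejects_unknown_block(medium_dataset, medium_global_fit):
    dataset, _ = medium_dataset
    with pytest.raises(ValueError):
        mlrt_test(medium_global_fit, "phi", dataset)


# ---------------------------------------------------------------------------
# Wald tests, interpretation, grouping
# ---------------------------------------------------------------------------

def test_wald_table_reproduces_z_and_multipliers(medium_global_fit):
    report = wald_partial(medium_global_fit)
    tab = report.table
    dim = 4 * (medium_global_fit.q + 1) + 3
    assert len(tab) == dim
    free = tab[np.isfinite(tab["se"])]
    assert np.allclose(free["z"], free["estimate"] / free["se"])
    assert np.allclose(free["p_value"],
                       2 * stats.norm.sf(np.abs(free["z"])))
    coef = tab[tab["block"].isin(["gamma1", "gamma2", "beta1", "beta2"])]
    assert np.allclose(coef["exp_estimate"], np.exp(coef["estimate"]))


def test_interpretation_labels_states_and_rounds(medium_global_fit):
    out = interpret_coefficients(wald_partial(medium_global_fit))
    assert set(out["state"]) == {"poisson_state_rate_multiplier",
                                 "zero_state_odds_multiplier"}
    assert np.allclose(out["multiplier"], np.exp(out["estimate"]))
    assert np.allclose(out["multiplier_rounded"],
                       np.round(np.exp(out["estimate"]), 3))


def test_significance_groups_partition_the_locations(small_dataset,
                                                     small_global_fit):
    dataset, _ = small_dataset
    gw = fit_gwbzigpr(dataset, KernelSpec("fixed_bisquare", 1.2),
                      global_fit=small_global_fit)
    groups = significance_groups(gw)
    for block in ("gamma1", "gamma2", "beta1", "beta2"):
        locs = [loc for g in groups[block] for loc in g["locations"]]
        assert sorted(locs) == sorted(dataset.ids.tolist())
        sizes = [len(g["locations"]) for g in groups[block]]
        assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def test_aicc_closed_form_and_limits():
    assert aicc(-100.0, 3, 30) == pytest.approx(206.0 + 24.0 / 26.0)
    assert aicc(-50.0, 0, 20) == pytest.approx(100.0)
    aic = -2 * (-100.0) + 2 * 5
    assert aicc(-100.0, 5, 40) > aic
    with pytest.raises(ValueError):
        aicc(-10.0, 10, 11)


def test_similarity_f_is_the_per_df_deviance_ratio():
    res = model_similarity_f(200.0, 10, 300.0, 30)
    assert res.statistic == pytest.approx((200.0 / 10) / (300.0 / 30))
    assert res.critical_value == pytest.approx(stats.f.ppf(0.95, 10, 30))
    assert model_similarity_f(100.0, 4, 250.0, 10).statistic == pytest.approx(1.0)
    with pytest.raises(ValueError):
        model_similarity_f(-1.0, 10, 300.0, 30)
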