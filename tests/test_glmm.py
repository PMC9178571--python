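"""Mixed-effects logistic model: quadrature accuracy, limits, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, log_expit

from milkpay.glmm import (
    GLMMFit,
    GLMMSpec,
    build_design,
    fit_glmm,
    logistic_irls,
    marginal_loglik,
    monthly_contrasts,
    predicted_proportions,
    simulate_binary_panel,
)


def trapezoid_marginal_loglik(theta, y, X, farm_idx, span=8.0, n_grid=40001):
    """Brute-force marginal log-likelihood by dense trapezoid integration."""
    beta, sigma = theta[:-1], np.exp(theta[-1])
    u = np.linspace(-span * sigma, span * sigma, n_grid)
    eta = (X @ beta)[:, None] + u[None, :]
    obs = y[:, None] * log_expit(eta) + (1 - y[:, None]) * log_expit(-eta)
    total = 0.0
    for i in range(int(farm_idx.max()) + 1):
        ll_u = obs[farm_idx == i].sum(axis=0)
        integrand = np.exp(ll_u) * np.exp(-0.5 * (u / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi)
        )
        total += np.log(np.trapezoid(integrand, u))
    return total


@pytest.mark.parametrize(
    "y,eta_slope,beta,sigma",
    [
        ([1, 0, 1], [0.0, 1.0, 2.0], [0.3, -0.4], 0.8),
        ([0, 0, 0], [0.0, 1.0, 2.0], [1.0, 0.5], 2.0),
        ([1, 1, 1, 0], [0.0, 0.5, 1.0, 1.5], [-1.2, 0.7], 0.3),
    ],
)
def test_quadrature_matches_dense_integration(y, eta_slope, beta, sigma):
    """Single-farm marginal likelihood agrees with trapezoid to <1e-6."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), eta_slope])
    theta = np.r_[beta, np.log(sigma)]
    farm = np.zeros(len(y), dtype=int)
    agq = marginal_loglik(theta, y, X, farm, n_quad=15)
    dense = trapezoid_marginal_loglik(theta, y, X, farm)
    assert abs(agq - dense) / abs(dense) < 1e-6


def test_zero_variance_data_matches_plain_logistic():
    """With no farm effect the GLMM collapses to ordinary logistic regression."""
    sm = pytest.importorskip("statsmodels.api")
    df = simulate_binary_panel(
        {"north": 80, "central": 80}, 6, intercept=0.8,
        region_effects={"central": -1.0}, sigma_u=0.0, seed=3,
    )
    fit = fit_glmm(df, GLMMSpec(compute_vcov=False))
    y, X, _, names, _ = build_design(df)
    # independent oracle: statsmodels GLM with the same design
    oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    assert fit.sigma_u < 0.05
    assert np.allclose(fit.beta.to_numpy(), oracle.params, atol=1e-3)
    # own IRLS agrees with the library fit too
    beta_irls, ll = logistic_irls(y, X)
    assert np.allclose(beta_irls, oracle.params, atol=1e-6)
    # nesting: the mixed fit can never fall below the plain-logistic loglik
    assert fit.loglik >= ll - 1e-6


def test_loglik_consistency_and_node_stability():
    df = simulate_binary_panel(
        {"north": 40, "central": 40}, 8, intercept=0.5,
        region_effects={"central": -0.8}, sigma_u=1.0, seed=11,
    )
    fit = fit_glmm(df, GLMMSpec(compute_vcov=False))
    y, X, farm_idx, _, _ = build_design(df)
    recomputed = marginal_loglik(fit.params, y, X, farm_idx, n_quad=15)
    assert fit.loglik == pytest.approx(recomputed, abs=1e-8)
    rich = marginal_loglik(fit.params, y, X, farm_idx, n_quad=41)
    assert abs(rich - fit.loglik) < 1e-4


def test_single_replicate_recovery():
    true_sigma, true_region = 1.0, -1.5
    df = simulate_binary_panel(
        {"north": 200, "central": 200}, 12, intercept=1.0,
        region_effects={"central": true_region}, sigma_u=true_sigma, seed=7,
    )
    fit = fit_glmm(df)
    assert fit.converged
    se = np.sqrt(fit.vcov.loc["region[central]", "region[central]"])
    assert abs(fit.beta["region[central]"] - true_region) < 4 * se
    assert abs(fit.sigma_u - true_sigma) < 0.35


def _toy_fit(beta_values, names, T=3, vcov_scale=0.04):
    p = len(names)
    return GLMMFit(
        beta=pd.Series(beta_values, index=names),
        sigma_u=0.5,
        loglik=-10.0,
        vcov=pd.DataFrame(vcov_scale * np.eye(p), index=names, columns=names),
        converged=True,
        n_farms=10,
        n_obs=30,
        n_quad=15,
        regions=["north", "central"],
        n_months=T,
    )


def test_predicted_proportions_inverse_link():
    names = ["(Intercept)", "region[central]", "t[2]", "t[3]",
             "region[central]:t[2]", "region[central]:t[3]"]
    flat = _toy_fit(np.zeros(6), names)
    assert np.allclose(predicted_proportions(flat)["probability"], 0.5)
    p0 = 0.887
    shifted = _toy_fit(np.r_[np.log(p0 / (1 - p0)), np.zeros(5)], names)
    pred = predicted_proportions(shifted)
    assert np.allclose(pred["probability"], p0)
    assert ((pred["probability"] > 0) & (pred["probability"] < 1)).all()
    assert len(pred) == 2 * 3


def test_contrast_adjustment_monotone_and_reproducible():
    df = simulate_binary_panel(
        {"north": 60, "central": 60}, 6, intercept=0.5,
        region_effects={"central": -0.7}, sigma_u=0.8, seed=21,
    )
    fit = fit_glmm(df)
    raw = monthly_contrasts(fit, adjustment="none")
    for method in ("sidak", "single_step_mvn"):
        adj = monthly_contrasts(fit, adjustment=method, seed=5)
        assert (adj["p_adj"] >= adj["p_raw"] - 1e-12).all()
        assert ((adj["p_adj"] >= 0) & (adj["p_adj"] <= 1)).all()
        assert np.allclose(adj["p_raw"], raw["p_raw"])
    a = monthly_contrasts(fit, adjustment="single_step_mvn", seed=5)
    b = monthly_contrasts(fit, adjustment="single_step_mvn", seed=5)
    pd.testing.assert_frame_equal(a, b)
    # Sidak matches its closed form
    sidak = monthly_contrasts(fit, adjustment="sidak")
    assert np.allclose(
        sidak["p_adj"],
        np.minimum(1.0, np.maximum(1 - (1 - sidak["p_raw"]) ** 6, sidak["p_raw"])),
    )
    assert raw.attrs["family_size"] == 6


def test_contrast_estimates_are_cellwise_logit_differences():
    """Contrast t equals the difference of the two cell linear predictors."""
    df = simulate_binary_panel(
        {"north": 50, "central": 50}, 4, intercept=0.3,
        region_effects={"central": -0.5}, sigma_u=0.6, seed=9,
    )
    fit = fit_glmm(df)
    pred = predicted_proportions(fit).set_index(["region", "month"])
    table = monthly_contrasts(fit, adjustment="none")
    for _, row in table.iterrows():
        t = int(row["month"])
        logit = lambda p: np.log(p / (1 - p))
        delta = logit(pred.loc[("central", t), "probability"]) - logit(
            pred.loc[("north", t), "probability"]
        )
        assert row["estimate"] == pytest.approx(delta, abs=1e-10)


def test_unbalanced_panel_and_empty_cell_handled():
    df = simulate_binary_panel(
        {"north": 30, "central": 30}, 5, sigma_u=0.5, seed=13
    )
    # remove every central observation of month 5 -> empty interaction cell
    df = df[~((df["region"] == "central") & (df["t"] == 5))].reset_index(drop=True)
    fit = fit_glmm(df, GLMMSpec(compute_vcov=False))
    assert fit.converged
    assert "region[central]:t[5]" not in fit.beta.index


def test_simulation_is_seed_deterministic():
    a = simulate_binary_panel({"north": 10}, 4, sigma_u=1.0, seed=2)
    b = simulate_binary_panel({"north": 10}, 4, sigma_u=1.0, seed=2)
    c = simulate_binary_panel({"north": 10}, 4, sigma_u=1.0, seed=3)
    pd.testing.assert_frame_equal(a, b)
    assert not a["y"].equals(c["y"])
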