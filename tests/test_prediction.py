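"""Empirical-Bayes effects, forecast formula, and error variances."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from emels import (
    EMELS,
    LongitudinalDataset,
    PersonSeries,
    Theta,
    conditional_loglik,
    evaluate_forecasts,
    fit_mem_ar1,
    forecast,
    forecast_error_variance,
    person_residuals,
    simulate_emels,
)
from emels.ar1 import ar1_covariance
from emels.model import LocationScaleResults


class _StubModel:
    """Duck-typed results carrier with externally fixed EB effects, for
    direct arithmetic checks of the forecast formula."""

    def _eb_for_series(self, results, series):
        return results._fixed_eb


def stub_results(beta, s0, r0, phi, eb, cov_beta=None, name="emels"):
    p = len(beta)
    n = p + 8
    cov = np.zeros((n, n))
    if cov_beta is not None:
        cov[:p, :p] = cov_beta
    res = LocationScaleResults(
        model=_StubModel(), model_name=name, beta=np.asarray(beta, float),
        beta_names=[f"b{i}" for i in range(p)], s0=s0, r0=r0,
        phi=np.asarray(phi, float), llf=0.0, n_params=n, nobs=10,
        converged=True, n_iter=1, loglik_trace=[0.0],
        theta_vector=np.zeros(n), cov_params_unconstrained=cov,
        se_available=True, k=1)
    return res


def test_person_residual_definitions(toy_dataset, toy_theta):
    s = toy_dataset.series[0]
    np.testing.assert_allclose(
        person_residuals(s, toy_theta.beta, 0.0),
        s.y - s.X @ toy_theta.beta)
    np.testing.assert_allclose(
        person_residuals(s, toy_theta.beta, 0.3, level1=False),
        s.y - 0.3)
    perfect = PersonSeries("p", s.times, s.X @ toy_theta.beta, s.X, s.Z)
    assert np.allclose(person_residuals(perfect, toy_theta.beta, 0.0), 0.0)


def test_forecast_formula_arithmetic():
    """x'beta = 2, b = 0.5, rho = 0.5, last residual = 1, H = 2
    gives 2 + 0.5 + 0.25 * 1 = 2.75."""
    res = stub_results([2.0], 0.0, np.arctanh(0.5), np.eye(3),
                       eb=None)
    res._fixed_eb = (np.array([0.5, 0.0, 0.0]), 1.0, 0.5)
    T = 4
    X = np.ones((T, 1))
    y = X @ res.beta + 0.5 + np.array([0.0, 0.0, 0.0, 1.0])
    s = PersonSeries("p", np.arange(1, T + 1), y, X, np.ones((T, 1)))
    fc = forecast(res, np.array([1.0]), H=2, task=1, series=s,
                  with_variance=False)
    assert fc.y_hat == pytest.approx(2.75, abs=1e-12)
    # large horizon: the residual carry-over vanishes
    fc_far = forecast(res, np.array([1.0]), H=200, task=1, series=s,
                      with_variance=False)
    assert fc_far.y_hat == pytest.approx(2.5, abs=1e-10)
    # task 2 is fixed effects only
    fc2 = forecast(res, np.array([1.0]), H=1, task=2, with_variance=False)
    assert fc2.y_hat == pytest.approx(2.0)
    with pytest.raises(ValueError, match="task 2"):
        forecast(res, np.array([1.0]), H=1, task=1, series=None)


def test_forecast_matches_gaussian_conditioning():
    """With known random effects, the one-step forecast equals the
    conditional mean of the multivariate normal given the history."""
    rng = np.random.default_rng(3)
    T = 12
    sigma2, rho, b = 0.8, 0.45, 0.6
    X = np.column_stack([np.ones(T + 1), rng.normal(size=T + 1)])
    beta = np.array([1.0, 0.5])
    res = stub_results(beta, np.log(sigma2), np.arctanh(rho), np.eye(3),
                       eb=None)
    res._fixed_eb = (np.array([b, 0.0, 0.0]), sigma2, rho)
    y = X[:T] @ beta + b + rng.normal(size=T)
    s = PersonSeries("p", np.arange(1, T + 1), y, X[:T], np.ones((T, 1)))
    fc = forecast(res, X[T], H=1, task=1, series=s, with_variance=False)
    S = ar1_covariance(sigma2, rho, T + 1)
    mean_hist = X[:T] @ beta + b
    cond_mean = (X[T] @ beta + b
                 + S[T, :T] @ np.linalg.solve(S[:T, :T], y - mean_hist))
    assert fc.y_hat == pytest.approx(cond_mean, abs=1e-10)


def test_task2_variance_term_sum():
    """Intercept-only, cov(beta)=0, phi_tau^2=1, stationary variance 1
    gives forecast-error variance 2."""
    res = stub_results([0.0], 0.0, 0.0, np.diag([1.0, 0.0, 0.0]),
                       eb=None, cov_beta=np.zeros((1, 1)))
    v = forecast_error_variance(res, None, np.array([1.0]), 1, 2)
    assert v == pytest.approx(2.0)


def test_task3_variance_below_task2():
    rng = np.random.default_rng(5)
    T = 10
    X = np.column_stack([np.ones(T), rng.normal(size=T)])
    y = rng.normal(size=T)
    s = PersonSeries("p", np.arange(1, T + 1), y, X, np.ones((T, 1)))
    res = stub_results([0.5, 0.2], np.log(0.6), np.arctanh(0.3),
                       np.diag([0.8, 0.0, 0.0]), eb=None,
                       cov_beta=np.zeros((2, 2)))
    x_f = np.array([1.0, 0.3])
    v3 = forecast_error_variance(res, s, x_f, 1, 3)
    v2 = forecast_error_variance(res, None, x_f, 1, 2)
    assert v3 <= v2 + 1e-12


def test_task1_variance_matches_dense_formula():
    """The O(T)-free implementation agrees with an explicit dense
    evaluation of the BLUP prediction-variance decomposition."""
    rng = np.random.default_rng(11)
    T, H = 7, 2
    sigma2, rho, phi_tau2 = 0.7, 0.35, 0.9
    X = np.column_stack([np.ones(T), rng.normal(size=T)])
    x_f = np.array([1.0, 0.4])
    y = rng.normal(size=T)
    s = PersonSeries("p", np.arange(1, T + 1), y, X, np.ones((T, 1)))
    cov_beta = np.array([[0.04, 0.01], [0.01, 0.09]])
    res = stub_results([0.5, 0.2], np.log(sigma2), np.arctanh(rho),
                       np.diag([phi_tau2, 0.0, 0.0]), eb=None,
                       cov_beta=cov_beta, name="mem_ar1")
    got = forecast_error_variance(res, s, x_f, H, 1)
    # dense reference
    Z = np.ones((T, 1))
    z_f = np.ones(1)
    Sig = ar1_covariance(sigma2, rho, T)
    V = phi_tau2 * Z @ Z.T + Sig
    sig2c = sigma2 / (1 - rho ** 2)
    cov_eps = sig2c * rho ** np.arange(T + H - 1, H - 1, -1)
    C = (z_f * phi_tau2) @ Z.T + cov_eps
    a = x_f - C @ np.linalg.solve(V, X)
    Phi_b = np.array([[phi_tau2]])
    shrink = Phi_b - Phi_b @ Z.T @ np.linalg.solve(V, Z) @ Phi_b
    ref = a @ cov_beta @ a + float(z_f @ shrink @ z_f) + sig2c
    assert got == pytest.approx(ref, abs=1e-10)


def test_eb_matches_dense_blup_formula():
    """Closed-form random-intercept estimates equal the textbook
    Phi Z' V^{-1} (y - X beta) evaluated with dense matrices."""
    ds, _ = simulate_emels(I=10, T=8, beta=[0.5, 0.2], s0=-0.3, r0=0.15,
                           phi=np.diag([0.7, 1e-12, 1e-12]), seed=17)
    res = fit_mem_ar1(ds, se=False)
    phi_tau2 = res.phi[0, 0]
    for i, s in enumerate(ds.series):
        V = phi_tau2 * np.ones((s.n_obs, s.n_obs)) + ar1_covariance(
            res.sigma2_eps, res.rho_eps, s.n_obs)
        ref = phi_tau2 * np.ones(s.n_obs) @ np.linalg.solve(
            V, s.y - s.X @ res.beta)
        assert res.random_effects.v[i, 0] == pytest.approx(ref, abs=1e-8)
        # the per-series path gives the same value
        v_hat, _, _ = res.eb_for_series(s)
        assert v_hat[0] == pytest.approx(ref, abs=1e-8)


def test_agh_posterior_mean_matches_linear_blup(toy_dataset):
    """With omega/iota variances near zero the quadrature posterior mean
    reduces to the linear-model BLUP (cross-route check)."""
    th = Theta.from_phi([1.0, 0.3], -0.4, 0.1, np.diag([0.6, 1e-10, 1e-10]))
    mod = EMELS(toy_dataset, quad_points=5)
    eng = mod.engine
    adapt = eng.adapt(th, mod.rule)
    v = eng.eb_means(th, adapt)
    ref = eng.eb_intercepts_linear(th.beta, th.s0, th.r0, 0.6)
    np.testing.assert_allclose(v[:, 0], ref, atol=1e-4)


def test_agh_posterior_mean_matches_grid_integration(toy_dataset, toy_theta):
    """1-person oracle: dense 3-D grid integration of the posterior mean."""
    s = toy_dataset.series[0]
    mod = EMELS(LongitudinalDataset([s], toy_dataset.predictor_names),
                quad_points=10)
    adapt = mod.engine.adapt(toy_theta, mod.rule)
    v_agh = mod.engine.eb_means(toy_theta, adapt)[0]
    grids = [np.linspace(-3.5, 3.5, 61) * np.sqrt(toy_theta.phi[j, j])
             for j in range(3)]
    G = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    logpost = np.array([
        conditional_loglik(s, v, toy_theta) for v in G
    ]) + multivariate_normal.logpdf(G, np.zeros(3), toy_theta.phi)
    w = np.exp(logpost - logpost.max())
    v_grid = (w[:, None] * G).sum(0) / w.sum()
    np.testing.assert_allclose(v_agh, v_grid, atol=2e-3)


def test_eb_shrinks_with_shorter_history():
    """A person observed once is shrunk harder than the same person
    observed fifty times (constant residual pattern)."""
    beta = np.array([0.0])
    res = None
    ds, _ = simulate_emels(I=4, T=50, beta=[0.0], s0=-0.5, r0=0.1,
                           phi=np.diag([0.6, 1e-12, 1e-12]), seed=2)
    fit = fit_mem_ar1(ds, se=False)
    T = 50
    X = np.ones((T, 1))
    y = np.full(T, 1.0)   # constant offset from the mean
    long = PersonSeries("c", np.arange(1, T + 1), y, X, np.ones((T, 1)))
    short = PersonSeries("c", np.arange(1, 2), y[:1], X[:1], np.ones((1, 1)))
    b_long, _, _ = fit.eb_for_series(long)
    b_short, _, _ = fit.eb_for_series(short)
    assert abs(b_short[0]) <= abs(b_long[0])


def test_evaluate_forecasts_arithmetic():
    from emels.prediction import ForecastResult
    fcs = [ForecastResult(1, 1, 1.0, 0.25), ForecastResult(1, 1, 2.0, 1.0)]
    mse, mse_se, msf = evaluate_forecasts([1.0, 4.0], fcs)
    assert mse == pytest.approx(2.0)
    assert msf == pytest.approx((0.5 + 1.0) / 2)
    mse0, _, _ = evaluate_forecasts([1.0, 2.0], fcs)
    assert mse0 == 0.0
    with pytest.raises(ValueError):
        evaluate_forecasts([], [])


def test_mse_converges_to_outcome_variance():
    rng = np.random.default_rng(0)
    from emels.prediction import ForecastResult
    y = rng.normal(size=4000)
    fcs = [ForecastResult(2, 1, 0.0, None) for _ in y]
    mse, mse_se, _ = evaluate_forecasts(y, fcs)
    assert mse == pytest.approx(1.0, abs=4 * mse_se)
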