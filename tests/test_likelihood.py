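"""Conditional density, AGH marginal likelihood, and its gradient."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from emels import (
    LongitudinalDataset,
    QuadratureRule,
    Theta,
    conditional_loglik,
    loglik_gradient,
    person_marginal_loglik,
    total_loglik,
)
from emels.ar1 import ar1_covariance
from emels.likelihood import AGHEngine


def mc_marginal_loglik(series, theta, n_draws, seed):
    """Plain Monte-Carlo integration over the N(0, Phi) prior.

    Returns (estimate, standard error of the log estimate).
    """
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(theta.phi)
    draws = rng.standard_normal((n_draws, 3)) @ L.T
    lls = np.array([conditional_loglik(series, v, theta) for v in draws])
    m = lls.max()
    w = np.exp(lls - m)
    est = m + np.log(w.mean())
    se = w.std() / (w.mean() * np.sqrt(n_draws))
    return est, se


def test_conditional_matches_dense_mvn(toy_dataset, toy_theta):
    for s in toy_dataset.series[:3]:
        v = np.array([0.4, -0.3, 0.25])
        mean = s.X @ toy_theta.beta + s.Z @ v[:1]
        cov = ar1_covariance(np.exp(toy_theta.s0 + v[1]),
                             np.tanh(toy_theta.r0 + v[2]), s.n_obs)
        ref = multivariate_normal.logpdf(s.y, mean, cov)
        assert conditional_loglik(s, v, toy_theta) == pytest.approx(
            ref, abs=1e-8)


def test_conditional_t1_density_at_mean(toy_theta):
    from emels.data import PersonSeries
    X = np.array([[1.0, 2.0]])
    y = X @ toy_theta.beta
    s = PersonSeries("p", [1], y, X, np.ones((1, 1)))
    sig2 = np.exp(toy_theta.s0)
    rho = np.tanh(toy_theta.r0)
    expected = -0.5 * np.log(2 * np.pi * sig2 / (1 - rho ** 2))
    assert conditional_loglik(s, np.zeros(3), toy_theta) == pytest.approx(
        expected, abs=1e-12)


def test_conditional_quadratic_form_scaling(toy_dataset, toy_theta):
    """Doubling the residual quadruples the quadratic-form part."""
    s = toy_dataset.series[0]
    v = np.zeros(3)
    base = conditional_loglik(s, v, toy_theta)
    shifted = Theta(toy_theta.beta.copy(), toy_theta.s0, toy_theta.r0,
                    toy_theta.phi_chol.copy())
    # construct a person whose residual is doubled
    from emels.data import PersonSeries
    mean = s.X @ toy_theta.beta
    s2 = PersonSeries(s.person_id, s.times, mean + 2 * (s.y - mean), s.X, s.Z)
    doubled = conditional_loglik(s2, v, shifted)
    sig2 = np.exp(toy_theta.s0)
    rho = np.tanh(toy_theta.r0)
    cov = ar1_covariance(sig2, rho, s.n_obs)
    const = -0.5 * (s.n_obs * np.log(2 * np.pi)
                    + np.linalg.slogdet(cov)[1])
    assert (doubled - const) == pytest.approx(4 * (base - const), rel=1e-10)


def test_degenerate_prior_reduces_to_conditional(toy_dataset, rule_q5):
    th = Theta.from_phi([1.0, 0.3], -0.5, 0.2, 1e-12 * np.eye(3))
    s = toy_dataset.series[0]
    assert person_marginal_loglik(s, th, rule_q5) == pytest.approx(
        conditional_loglik(s, np.zeros(3), th), abs=1e-4)


@pytest.fixture(scope="module")
def short_toy(toy_theta):
    """Two persons x 3 occasions -- short series keep the integrand close
    to the Gaussian prior, where both AGH and plain MC converge fast."""
    from emels import simulate_emels
    ds, _ = simulate_emels(I=2, T=3, beta=toy_theta.beta, s0=toy_theta.s0,
                           r0=toy_theta.r0, phi=toy_theta.phi, seed=5)
    return ds


def test_agh_matches_monte_carlo(short_toy, toy_theta):
    r10 = QuadratureRule.gauss_hermite(10, 3)
    for s in short_toy.series:
        agh = person_marginal_loglik(s, toy_theta, r10)
        mc, se = mc_marginal_loglik(s, toy_theta, 200_000, seed=7)
        assert abs(agh - mc) < 3 * se


def test_quadrature_refinement_is_stable(short_toy):
    # moderate heterogeneity: with a large autocorrelation variance the
    # integrand has heavy tails in iota and needs more nodes
    th = Theta.from_phi([1.0, 0.3], -0.5, 0.2, np.diag([0.5, 0.2, 0.1]))
    r10 = QuadratureRule.gauss_hermite(10, 3)
    r20 = QuadratureRule.gauss_hermite(20, 3)
    for s in short_toy.series:
        a = person_marginal_loglik(s, th, r10)
        b = person_marginal_loglik(s, th, r20)
        assert abs(a - b) < 1e-4


def test_total_is_additive_and_order_invariant(toy_dataset, toy_theta,
                                               rule_q5):
    ll = total_loglik(toy_dataset, toy_theta, rule_q5)
    parts = sum(person_marginal_loglik(s, toy_theta, rule_q5)
                for s in toy_dataset.series)
    assert ll == pytest.approx(parts, abs=1e-8)
    # duplicated person doubles the contribution
    dup = LongitudinalDataset(
        [toy_dataset.series[0]], toy_dataset.predictor_names)
    two = LongitudinalDataset(
        [toy_dataset.series[0],
         type(toy_dataset.series[0])(
             "copy", toy_dataset.series[0].times, toy_dataset.series[0].y,
             toy_dataset.series[0].X, toy_dataset.series[0].Z)],
        toy_dataset.predictor_names)
    assert total_loglik(two, toy_theta, rule_q5) == pytest.approx(
        2 * total_loglik(dup, toy_theta, rule_q5), abs=1e-6)
    # permutation invariance
    perm = LongitudinalDataset(toy_dataset.series[::-1],
                               toy_dataset.predictor_names)
    assert total_loglik(perm, toy_theta, rule_q5) == pytest.approx(
        ll, abs=1e-6)


def test_empty_dataset_errors(toy_theta, rule_q5):
    empty = LongitudinalDataset([], ["const", "x1"])
    with pytest.raises(ValueError):
        total_loglik(empty, toy_theta, rule_q5)


def test_linear_special_case_closed_form(toy_dataset, rule_q4):
    """With the omega/iota variances at zero the AGH marginal equals the
    closed-form normal likelihood with V = phi_tau^2 11' + Sigma."""
    th = Theta.from_phi([1.0, 0.3], -0.4, 0.15,
                        np.diag([0.6, 1e-12, 1e-12]))
    agh = total_loglik(toy_dataset, th, rule_q4)
    eng = AGHEngine(toy_dataset)
    closed = eng.marginal_loglik_linear(th.beta, th.s0, th.r0, 0.6)
    assert agh == pytest.approx(closed, abs=1e-5)
    # and the closed form itself matches dense multivariate-normal algebra
    dense = 0.0
    for s in toy_dataset.series:
        V = 0.6 * np.ones((s.n_obs, s.n_obs)) + ar1_covariance(
            np.exp(th.s0), np.tanh(th.r0), s.n_obs)
        dense += multivariate_normal.logpdf(s.y, s.X @ th.beta, V)
    assert closed == pytest.approx(dense, abs=1e-8)


def test_gradient_matches_finite_differences(two_person_toy, toy_theta,
                                             rule_q4):
    """At a point away from the optimum (components O(1) or larger) the
    gradient agrees with an independently stepped central difference."""
    th = Theta.from_phi(toy_theta.beta + 0.25, toy_theta.s0 + 0.3,
                        toy_theta.r0 - 0.2, toy_theta.phi)
    g = loglik_gradient(two_person_toy, th, rule_q4, h=1e-5)
    x0 = th.to_vector()
    f = lambda x: total_loglik(
        two_person_toy, Theta.from_vector(x, 2, 1), rule_q4)
    ref = np.empty_like(x0)
    for i in range(x0.size):
        h = 4e-6 * (1 + abs(x0[i]))
        e = np.zeros_like(x0)
        e[i] = h
        ref[i] = (f(x0 + e) - f(x0 - e)) / (2 * h)
    assert np.max(np.abs(g - ref) / np.maximum(np.abs(ref), 1.0)) < 1e-4
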