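"""Empirical-Bayes effects, H-step forecasting and forecast evaluation.

Three prediction tasks are supported:

* **Task 1** -- forecast a future occasion of a *training* person:
  ``y_hat = x'beta + z'b_i + rho_i**H * eps_hat_{i,T}``, where b_i is the
  person's empirical-Bayes effect, eps_hat_{i,T} the last Level-1 residual,
  and rho_i the person-specific autocorrelation (tanh(r0 + iota_i) under
  the location-scale model, tanh(r0) under the linear model).
* **Task 2** -- a new person with no history: fixed effects only,
  ``y_hat = x'beta``.
* **Task 3** -- a new person *with* history: estimate the random effects
  from that history using the training-sample parameters, then apply the
  Task-1 formula.

Forecast-error variances follow the standard BLUP prediction-variance
decomposition: fixed-effect estimation error, random-effect shrinkage
error, and the residual innovation, with the residual covariance taken as
the stationary AR(1) kernel.  Under the location-scale model the
person-specific (sigma2_i, rho_i) empirical-Bayes plug-ins are treated as
known.  Trees have no established forecast-error variance; tree results
report only point forecasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ar1 import ar1_covariance
from .data import PersonSeries
from .likelihood import QuadratureRule
from .model import LocationScaleResults
from .params import Theta

__all__ = [
    "ForecastResult",
    "eb_estimate",
    "person_residuals",
    "forecast",
    "forecast_error_variance",
    "evaluate_forecasts",
]


@dataclass
class ForecastResult:
    """One H-step point forecast with (optional) error variance."""

    task: int
    H: int
    y_hat: float
    var_hat: float | None
    person_id: object = None

    @property
    def sigma_F(self) -> float | None:
        return None if self.var_hat is None else float(np.sqrt(self.var_hat))


def eb_estimate(series: PersonSeries, results: LocationScaleResults):
    """Empirical-Bayes (v_hat, sigma2_i, rho_i) for a series under fitted
    parameters (posterior mean via the person's adapted quadrature; closed
    form for the linear AR(1) model)."""
    return results.eb_for_series(series)


def person_residuals(series: PersonSeries, beta: np.ndarray, b,
                     level1: bool = True) -> np.ndarray:
    """Residuals given random effects.

    ``level1=True`` returns y - X beta - Z b (the Level-1 residuals used in
    the forecast formula); ``level1=False`` returns y - Z b (fixed part
    retained, the target of the tree-building step).
    """
    b = np.atleast_1d(np.asarray(b, float))
    r = series.y - series.Z @ b
    if level1:
        r = r - series.X @ beta
    return r


def _stationary_var(sigma2: float, rho: float) -> float:
    return sigma2 / (1.0 - rho ** 2)


def forecast_error_variance(
    results: LocationScaleResults,
    series: PersonSeries | None,
    x_future: np.ndarray,
    H: int,
    task: int,
    z_future: np.ndarray | None = None,
    sigma2_i: float | None = None,
    rho_i: float | None = None,
) -> float:
    """Forecast-error variance for one H-step forecast.

    Tasks 1/3 use the conditional-prediction decomposition with
    V_i = Z Phi_b Z' + Sigma_i and the AR(1) cross-covariance
    cov(eps_{T+H}, eps) = sigma2_c * (rho**(T+H-1), ..., rho**H); Task 2
    drops every history term.  Person-specific (sigma2_i, rho_i) may be
    supplied as plug-ins (location-scale model); defaults are the
    population values exp(s0), tanh(r0).
    """
    if results.cov_beta is None:
        raise ValueError("cov(beta) unavailable: fit without standard errors")
    x_future = np.asarray(x_future, float)
    z_future = np.ones(results.k) if z_future is None else \
        np.atleast_1d(np.asarray(z_future, float))
    sigma2 = results.sigma2_eps if sigma2_i is None else float(sigma2_i)
    rho = results.rho_eps if rho_i is None else float(rho_i)
    phi_b = results.phi_b
    sig2_c = _stationary_var(sigma2, rho)
    if task == 2:
        return float(
            x_future @ results.cov_beta @ x_future
            + z_future @ phi_b @ z_future
            + sig2_c
        )
    if series is None:
        raise ValueError("tasks 1/3 need the person's history")
    T = series.n_obs
    V = series.Z @ phi_b @ series.Z.T + ar1_covariance(sigma2, rho, T)
    Vinv_X = np.linalg.solve(V, series.X)
    Vinv_Z = np.linalg.solve(V, series.Z)
    cov_eps = sig2_c * rho ** np.arange(T + H - 1, H - 1, -1)
    C = z_future @ phi_b @ series.Z.T + cov_eps
    a = x_future - C @ Vinv_X
    term1 = float(a @ results.cov_beta @ a)
    shrink = phi_b - phi_b @ series.Z.T @ Vinv_Z @ phi_b
    term2 = float(z_future @ shrink @ z_future)
    return term1 + term2 + sig2_c


def forecast(
    results: LocationScaleResults,
    x_future: np.ndarray,
    H: int = 1,
    task: int = 2,
    series: PersonSeries | None = None,
    z_future: np.ndarray | None = None,
    with_variance: bool = True,
) -> ForecastResult:
    """H-step forecast for one person under a fitted model.

    ``series`` is the person's observed history (required for tasks 1 and
    3; for task 1 it is the person's training series, for task 3 the new
    person's past).  ``x_future``/``z_future`` are the known design rows of
    the occasion to forecast.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    if task not in (1, 2, 3):
        raise ValueError("task must be 1, 2 or 3")
    x_future = np.asarray(x_future, float)
    z_future = np.ones(results.k) if z_future is None else \
        np.atleast_1d(np.asarray(z_future, float))
    pid = series.person_id if series is not None else None
    if task == 2:
        y_hat = float(x_future @ results.beta)
        var = forecast_error_variance(results, None, x_future, H, 2,
                                      z_future) if with_variance else None
        return ForecastResult(2, H, y_hat, var, pid)
    if series is None or series.n_obs < 1:
        raise ValueError("tasks 1/3 require past observations; "
                         "use task 2 for persons without history")
    v_hat, sigma2_i, rho_i = results.eb_for_series(series)
    b_hat = v_hat[: results.k]
    eps = person_residuals(series, results.beta, b_hat, level1=True)
    y_hat = float(
        x_future @ results.beta + z_future @ b_hat + rho_i ** H * eps[-1]
    )
    var = None
    if with_variance:
        plug = (sigma2_i, rho_i) if results.model_name == "emels" else \
            (None, None)
        var = forecast_error_variance(
            results, series, x_future, H, task, z_future,
            sigma2_i=plug[0], rho_i=plug[1],
        )
    return ForecastResult(task, H, y_hat, var, pid)


def evaluate_forecasts(observed, forecasts):
    """Accuracy and precision summary over aligned forecast pairs.

    Returns (mse, mse_se, mean_sigma_F): the mean squared forecast error,
    its standard error (SD of the squared errors / sqrt(m)), and the mean
    forecast-error standard deviation (None if no forecast carries one).
    """
    observed = np.asarray(observed, float)
    if len(forecasts) == 0 or observed.size != len(forecasts):
        raise ValueError("observed and forecasts must align and be non-empty")
    y_hat = np.array([f.y_hat for f in forecasts])
    sq = (observed - y_hat) ** 2
    mse = float(sq.mean())
    mse_se = float(sq.std(ddof=1) / np.sqrt(sq.size)) if sq.size > 1 else 0.0
    sigmas = [f.sigma_F for f in forecasts if f.var_hat is not None]
    mean_sigma = float(np.mean(sigmas)) if sigmas else None
    return mse, mse_se, mean_sigma
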