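"""Maximum-likelihood fitting of the extended mixed-effect location-scale
model (E-MELS) and its nested AR(1) linear mixed model.

The interface follows the Model/Results convention: build a model object
from a :class:`~emels.data.LongitudinalDataset` (or a long-format
DataFrame), call :meth:`fit`, and read estimates, standard errors and
information criteria off the returned results object.

    >>> res = EMELS(train).fit()
    >>> res.summary()
    >>> res.random_effects.rho      # person-specific autocorrelations

Estimation is marginal ML: the random effects (intercept, log residual
variance, atanh autocorrelation) are integrated out with adaptive
Gauss-Hermite quadrature and the marginal log-likelihood is maximized by
L-BFGS on an unconstrained parametrization (log-Cholesky for Phi).  The
quadrature adaptation (per-person posterior mode and curvature) is
refreshed between L-BFGS cycles, which keeps the inner objective smooth.
The linear mixed model with AR(1) errors is the special case with the
omega/iota variances pinned at zero; it has a closed-form marginal normal
likelihood and needs no quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import LongitudinalDataset, PersonSeries, dataset_from_frame
from .likelihood import AGHEngine, QuadratureRule
from .numdiff import central_gradient, central_hessian
from .params import Theta

__all__ = [
    "EMELS",
    "MixedAR1",
    "LocationScaleResults",
    "RandomEffects",
    "fit_emels",
    "fit_mem_ar1",
    "standard_errors",
    "lr_test",
    "initial_theta",
]


@dataclass
class RandomEffects:
    """Per-person empirical-Bayes random effects and derived quantities."""

    person_ids: list
    v: np.ndarray        # (I, k+2): (b_i, omega_i, iota_i)
    sigma2: np.ndarray   # exp(s0 + omega_i)
    rho: np.ndarray      # tanh(r0 + iota_i)

    def for_person(self, person_id):
        i = self.person_ids.index(person_id)
        return self.v[i], float(self.sigma2[i]), float(self.rho[i])


def initial_theta(ds: LongitudinalDataset, k: int = 1,
                  phi_scale: float = 0.1) -> Theta:
    """Cheap consistent starting values: pooled OLS for beta, the pooled
    residual variance / lag-1 autocorrelation for (s0, r0), 0.1*I for Phi."""
    X = np.vstack([s.X for s in ds.series])
    y = np.concatenate([s.y for s in ds.series])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    num = 0.0
    den = 0.0
    for s in ds.series:
        r = s.y - s.X @ beta
        num += float(r[:-1] @ r[1:])
        den += float(r @ r)
    resvar = max(den / max(len(y), 1), 1e-8)
    rho0 = np.clip(num / den if den > 0 else 0.0, -0.95, 0.95)
    s0 = float(np.log(resvar))
    r0 = float(np.arctanh(rho0))
    phi = phi_scale * np.eye(k + 2)
    return Theta.from_phi(beta, s0, r0, phi, k=k)


@dataclass
class LocationScaleResults:
    """Estimates, uncertainties and diagnostics of a fitted model.

    ``phi`` is always the full (k+2) x (k+2) random-effect covariance; for
    the linear AR(1) mixed model the omega/iota rows are structurally zero.
    """

    model: object
    model_name: str
    beta: np.ndarray
    beta_names: list
    s0: float
    r0: float
    phi: np.ndarray
    llf: float
    n_params: int
    nobs: int
    converged: bool
    n_iter: int
    loglik_trace: list
    theta_vector: np.ndarray
    cov_params_unconstrained: np.ndarray | None = None
    se_available: bool = False
    random_effects: RandomEffects | None = None
    k: int = 1

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + np.log(self.nobs) * self.n_params

    @property
    def sigma2_eps(self) -> float:
        """Residual-variance intercept exp(s0)."""
        return float(np.exp(self.s0))

    @property
    def rho_eps(self) -> float:
        """Autocorrelation intercept tanh(r0)."""
        return float(np.tanh(self.r0))

    @property
    def phi_b(self) -> np.ndarray:
        return self.phi[: self.k, : self.k]

    @property
    def cov_beta(self) -> np.ndarray | None:
        if self.cov_params_unconstrained is None:
            return None
        p = len(self.beta)
        return self.cov_params_unconstrained[:p, :p]

    # -- reporting ---------------------------------------------------------
    def _report_map(self, x: np.ndarray) -> np.ndarray:
        th = self.model._theta_from_vector(x)
        phi = th["phi"]
        vals = list(th["beta"])
        vals.append(phi[0, 0])
        vals.append(np.exp(th["s0"]))
        vals.append(np.tanh(th["r0"]))
        if self.model_name == "emels":
            vals += [phi[1, 1], phi[2, 2], phi[0, 1], phi[0, 2], phi[1, 2]]
        return np.array(vals)

    def _report_names(self) -> list:
        names = list(self.beta_names)
        names += ["intercept_variance", "resid_variance_intercept",
                  "autocorr_intercept"]
        if self.model_name == "emels":
            names += ["resid_variance_variance", "autocorr_variance",
                      "cov_tau_omega", "cov_tau_iota", "cov_omega_iota"]
        return names

    def report_table(self) -> pd.DataFrame:
        """Parameter summary on the reporting scale (variances via exp,
        autocorrelation via tanh), with delta-method standard errors."""
        est = self._report_map(self.theta_vector)
        se = np.full(est.shape, np.nan)
        if self.se_available:
            J = np.column_stack([
                central_gradient(lambda x, i=i: self._report_map(x)[i],
                                 self.theta_vector)
                for i in range(est.size)
            ]).T
            cov = J @ self.cov_params_unconstrained @ J.T
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return pd.DataFrame({"estimate": est, "se": se},
                            index=self._report_names())

    @property
    def bse(self) -> pd.Series:
        return self.report_table()["se"]

    def summary(self) -> str:
        tab = self.report_table()
        lines = [
            f"{self.model_name.upper()} fit: {len(self.beta)} fixed effects, "
            f"{self.nobs} observations, "
            f"{'converged' if self.converged else 'NOT converged'} "
            f"in {self.n_iter} iterations",
            tab.to_string(float_format=lambda v: f"{v: .4f}"),
            f"logL = {self.llf:.3f}   AIC = {self.aic:.2f}   "
            f"BIC = {self.bic:.2f}   (n_params = {self.n_params})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "beta": dict(zip(self.beta_names, map(float, self.beta))),
            "s0": self.s0,
            "r0": self.r0,
            "phi": self.phi.tolist(),
            "loglik": self.llf,
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_params": self.n_params,
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
        }

    # -- random effects for arbitrary persons (Tasks 1 and 3) --------------
    def eb_for_series(self, series: PersonSeries) -> tuple:
        """Empirical-Bayes (v_hat, sigma2_i, rho_i) for any person's series
        evaluated at the training estimates."""
        return self.model._eb_for_series(self, series)


class EMELS:
    """Extended mixed-effect location-scale model with AR(1) residuals.

    Random effects: the mean-structure intercept tau_i, the log residual
    variance deviation omega_i, and the atanh autocorrelation deviation
    iota_i, jointly N(0, Phi).  Only the random-intercept mean structure
    (k=1) is supported.

    Parameters
    ----------
    dataset : LongitudinalDataset
    k : int
        Number of mean-structure random effects; must be 1.
    quad_points : int
        Gauss-Hermite nodes per dimension (default 10; 4-5 is usually
        adequate and much faster for exploration).
    """

    name = "emels"

    def __init__(self, dataset: LongitudinalDataset, k: int = 1,
                 quad_points: int = 10):
        if k != 1:
            raise NotImplementedError("only the random-intercept model (k=1)")
        self.dataset = dataset
        self.k = k
        self.quad_points = quad_points
        self.engine = AGHEngine(dataset)
        self.rule = QuadratureRule.gauss_hermite(quad_points, d=k + 2)
        self.n_beta = self.engine.P

    @classmethod
    def from_dataframe(cls, df, outcome_col, id_col, time_col, predictor_cols,
                       **kw) -> "EMELS":
        return cls(dataset_from_frame(df, outcome_col, id_col, time_col,
                                      predictor_cols), **kw)

    def _theta_from_vector(self, x):
        th = Theta.from_vector(x, self.n_beta, self.k)
        return {"beta": th.beta, "s0": th.s0, "r0": th.r0, "phi": th.phi,
                "theta": th}

    def loglik(self, theta: Theta) -> float:
        eng = self.engine
        return eng.loglik(theta, eng.adapt(theta, self.rule))

    def fit(self, start: Theta | None = None, tol: float = 1e-6,
            theta_tol: float = 3e-7, max_outer: int = 60,
            inner_maxiter: int = 60, se: bool = True,
            fd_step: float = 1e-5) -> LocationScaleResults:
        """Maximize the AGH marginal log-likelihood.

        Alternates between refreshing the per-person quadrature adaptation
        and L-BFGS cycles on the fixed-adaptation objective.  The iteration
        is a fixed-point map in theta and converges linearly near the
        optimum; it stops when the largest parameter movement in a cycle
        falls below ``theta_tol`` (or, as a weaker criterion, when the
        log-likelihood change falls below ``tol`` with parameters moving
        less than 1e-3).  Non-convergence is flagged, not raised.
        """
        eng = self.engine
        theta = start.copy() if start is not None else initial_theta(
            self.dataset, self.k)
        adapt = eng.adapt(theta, self.rule)
        ll = eng.loglik(theta, adapt)
        trace = [ll]
        converged = False
        n_iter = 0
        x = theta.to_vector()
        for outer in range(max_outer):
            obj, grad = self._fixed_adapt_objective(adapt, fd_step)
            res = optimize.minimize(
                obj, x, jac=grad, method="L-BFGS-B",
                options={"maxiter": inner_maxiter, "ftol": 0.0,
                         "gtol": 1e-6},
            )
            dx = float(np.max(np.abs(res.x - x)))
            x = res.x
            theta = Theta.from_vector(x, self.n_beta, self.k)
            adapt = eng.adapt(theta, self.rule, warm_modes=adapt.modes)
            ll_new = eng.loglik(theta, adapt)
            trace.append(ll_new)
            n_iter = outer + 1
            # theta movement is the primary criterion: the loglik change
            # flattens out well before the fixed point is reached
            if dx < theta_tol or (
                    abs(ll_new - ll) < tol * (abs(ll_new) + 1.0)
                    and dx < 10 * theta_tol):
                converged = True
                ll = ll_new
                break
            ll = ll_new
        return self._build_results(theta, adapt, ll, trace, converged,
                                   n_iter, se)

    def _fixed_adapt_objective(self, adapt, fd_step):
        eng = self.engine
        cache = {}

        def nll(x):
            key = x.tobytes()
            if key not in cache:
                th = Theta.from_vector(x, self.n_beta, self.k)
                cache[key] = -eng.loglik(th, adapt)
                if len(cache) > 256:
                    cache.pop(next(iter(cache)))
            return cache[key]

        def grad(x):
            return central_gradient(nll, x, h=fd_step)

        return nll, grad

    def _build_results(self, theta, adapt, ll, trace, converged, n_iter, se):
        eng = self.engine
        n_params = theta.n_free  # (p+1) + 2 + (k+2)(k+3)/2
        cov = None
        se_ok = False
        if se:
            obj, _ = self._fixed_adapt_objective(adapt, 1e-5)
            H = central_hessian(obj, theta.to_vector())
            try:
                cov = np.linalg.inv(H)
                se_ok = bool(np.all(np.diag(cov) > 0))
            except np.linalg.LinAlgError:
                cov = None
        v = eng.eb_means(theta, adapt)
        re = RandomEffects(
            person_ids=[s.person_id for s in self.dataset.series],
            v=v,
            sigma2=np.exp(np.clip(theta.s0 + v[:, self.k], -30, 30)),
            rho=np.tanh(theta.r0 + v[:, self.k + 1]),
        )
        return LocationScaleResults(
            model=self, model_name=self.name,
            beta=theta.beta.copy(), beta_names=list(self.dataset.predictor_names),
            s0=theta.s0, r0=theta.r0, phi=theta.phi, llf=ll,
            n_params=n_params, nobs=self.dataset.n_total,
            converged=converged, n_iter=n_iter, loglik_trace=trace,
            theta_vector=theta.to_vector(),
            cov_params_unconstrained=cov, se_available=se_ok,
            random_effects=re, k=self.k,
        )

    def _eb_for_series(self, results, series: PersonSeries):
        sub = LongitudinalDataset(
            [series], [f"c{j}" for j in range(series.X.shape[1])]
        )
        eng = AGHEngine(sub)
        theta = Theta.from_vector(results.theta_vector, self.n_beta, self.k)
        adapt = eng.adapt(theta, self.rule)
        v = eng.eb_means(theta, adapt)[0]
        sigma2 = float(np.exp(np.clip(theta.s0 + v[self.k], -30, 30)))
        rho = float(np.tanh(theta.r0 + v[self.k + 1]))
        return v, sigma2, rho


class MixedAR1:
    """Linear mixed model with random intercept and AR(1) residuals.

    The special case of the location-scale model with the omega and iota
    variances fixed at zero; the marginal likelihood is normal with
    V_i = phi_tau^2 11' + Sigma and is maximized directly (no quadrature).
    Parametrized through the same links: sigma2 = exp(s0), rho = tanh(r0),
    phi_tau^2 = exp(2 c).
    """

    name = "mem_ar1"

    def __init__(self, dataset: LongitudinalDataset, k: int = 1):
        if k != 1:
            raise NotImplementedError("only the random-intercept model (k=1)")
        self.dataset = dataset
        self.k = k
        self.engine = AGHEngine(dataset)
        self.n_beta = self.engine.P

    @classmethod
    def from_dataframe(cls, df, outcome_col, id_col, time_col, predictor_cols,
                       **kw) -> "MixedAR1":
        return cls(dataset_from_frame(df, outcome_col, id_col, time_col,
                                      predictor_cols), **kw)

    def _theta_from_vector(self, x):
        p = self.n_beta
        phi = np.zeros((3, 3))
        phi[0, 0] = np.exp(2.0 * np.clip(x[p + 2], -20, 20))
        return {"beta": x[:p], "s0": float(x[p]), "r0": float(x[p + 1]),
                "phi": phi}

    def loglik_vector(self, x) -> float:
        p = self.n_beta
        phi_tau2 = np.exp(2.0 * np.clip(x[p + 2], -20, 20))
        return self.engine.marginal_loglik_linear(
            x[:p], float(x[p]), float(x[p + 1]), phi_tau2)

    def fit(self, start=None, tol: float = 1e-9, se: bool = True,
            maxiter: int = 500) -> LocationScaleResults:
        if start is None:
            th0 = initial_theta(self.dataset, 1)
            x0 = np.concatenate([th0.beta, [th0.s0, th0.r0,
                                            0.5 * np.log(0.1)]])
        else:
            x0 = np.asarray(start, float)
        nll = lambda x: -self.loglik_vector(x)
        grad = lambda x: central_gradient(nll, x, h=1e-6)
        res = optimize.minimize(
            nll, x0, jac=grad, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-8},
        )
        x = res.x
        ll = -res.fun
        p = self.n_beta
        phi = np.zeros((3, 3))
        phi_tau2 = float(np.exp(2.0 * x[p + 2]))
        phi[0, 0] = phi_tau2
        cov = None
        se_ok = False
        if se:
            H = central_hessian(nll, x)
            try:
                cov = np.linalg.inv(H)
                se_ok = bool(np.all(np.diag(cov) > 0))
            except np.linalg.LinAlgError:
                cov = None
        b = self.engine.eb_intercepts_linear(x[:p], x[p], x[p + 1], phi_tau2)
        I = self.dataset.n_persons
        v = np.column_stack([b, np.zeros(I), np.zeros(I)])
        re = RandomEffects(
            person_ids=[s.person_id for s in self.dataset.series],
            v=v,
            sigma2=np.full(I, float(np.exp(x[p]))),
            rho=np.full(I, float(np.tanh(x[p + 1]))),
        )
        return LocationScaleResults(
            model=self, model_name=self.name,
            beta=x[:p].copy(), beta_names=list(self.dataset.predictor_names),
            s0=float(x[p]), r0=float(x[p + 1]), phi=phi, llf=ll,
            n_params=p + 3, nobs=self.dataset.n_total,
            converged=bool(res.success), n_iter=int(res.nit),
            loglik_trace=[ll], theta_vector=x.copy(),
            cov_params_unconstrained=cov, se_available=se_ok,
            random_effects=re, k=1,
        )

    def _eb_for_series(self, results, series: PersonSeries):
        sub = LongitudinalDataset(
            [series], [f"c{j}" for j in range(series.X.shape[1])]
        )
        eng = AGHEngine(sub)
        phi_tau2 = float(results.phi[0, 0])
        b = eng.eb_intercepts_linear(results.beta, results.s0, results.r0,
                                     phi_tau2)[0]
        return (np.array([b, 0.0, 0.0]), results.sigma2_eps, results.rho_eps)


# ---------------------------------------------------------------------------
# functional wrappers and the likelihood-ratio test
# ---------------------------------------------------------------------------

def fit_emels(ds: LongitudinalDataset, k: int = 1, quad_points: int = 10,
              init: Theta | None = None, tol: float = 1e-6,
              **kw) -> LocationScaleResults:
    return EMELS(ds, k=k, quad_points=quad_points).fit(start=init, tol=tol,
                                                       **kw)


def fit_mem_ar1(ds: LongitudinalDataset, k: int = 1,
                tol: float = 1e-9, **kw) -> LocationScaleResults:
    return MixedAR1(ds, k=k).fit(tol=tol, **kw)


def standard_errors(fit: LocationScaleResults) -> pd.Series:
    """Delta-method standard errors on the reporting scale (NaN when the
    observed information was singular)."""
    return fit.report_table()["se"]


def lr_test(fit_full: LocationScaleResults,
            fit_nested: LocationScaleResults):
    """Likelihood-ratio test of nested fits; plain chi-square reference
    (no boundary mixture correction).  Returns (statistic, df, p)."""
    stat = 2.0 * (fit_full.llf - fit_nested.llf)
    if stat < -1e-6:
        raise ValueError(
            "full-model log-likelihood below nested model's: optimization "
            f"failure (statistic {stat:.3g})"
        )
    stat = max(stat, 0.0)
    df = fit_full.n_params - fit_nested.n_params
    p = float(stats.chi2.sf(stat, df)) if df > 0 else (1.0 if stat == 0 else 0.0)
    return float(stat), int(df), p
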