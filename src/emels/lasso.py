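"""L1-penalized estimation of the location-scale mixed model.

The penalized objective is the marginal log-likelihood minus
``lam * sum_j |beta_j|`` over the slope coefficients (the intercept, s0,
r0 and the random-effect covariance are never penalized).  It is maximized
by block coordinate ascent:

* **beta block** -- proximal-gradient steps: a gradient step on the
  smooth log-likelihood followed by soft-thresholding of the penalized
  coordinates, with backtracking on the penalized objective.  The proximal
  map produces exact zeros, so the reported support is bit-exact sparse.
* **gamma block** -- quasi-Newton (L-BFGS) maximization over
  (s0, r0, Phi) at fixed beta.

A lambda path is fitted in increasing order with warm starts; AIC/BIC with
``df = #nonzero beta + 2 + #free Phi parameters`` select the penalty, and
an unpenalized refit on the selected support supplies the model used for
forecasting.  ``inner='mem'`` runs the same scheme on the AR(1) linear
mixed model likelihood (no quadrature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import INTERCEPT_NAME, LongitudinalDataset
from .likelihood import AGHEngine, QuadratureRule
from .model import EMELS, MixedAR1, LocationScaleResults, initial_theta
from .numdiff import central_gradient
from .params import Theta

__all__ = ["LassoEMELS", "LassoFit", "LassoPath", "fit_lasso_emels",
           "lambda_path", "refit_selected", "default_lambda_grid"]


def default_lambda_grid(n: int = 50, lo: float = 0.0,
                        hi: float = 500.0) -> np.ndarray:
    """The default penalty grid: ``n`` equally spaced values on [lo, hi]."""
    return np.linspace(lo, hi, n)


def _soft_threshold(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


@dataclass
class LassoFit:
    """One penalized fit: sparse beta plus the nuisance block."""

    lam: float
    beta: np.ndarray
    beta_names: list
    gamma: np.ndarray          # (s0, r0, phi parameters) on fitting scale
    loglik: float              # unpenalized marginal logL at the estimates
    penalized_loglik: float
    df: int
    nobs: int
    converged: bool
    n_cycles: int
    inner: str

    @property
    def aic(self) -> float:
        return -2.0 * self.penalized_loglik + 2.0 * self.df

    @property
    def bic(self) -> float:
        return -2.0 * self.penalized_loglik + np.log(self.nobs) * self.df

    @property
    def nonzero(self) -> list:
        return [n for n, b in zip(self.beta_names, self.beta) if b != 0.0]

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.beta != 0.0))


class LassoEMELS:
    """Lasso-penalized location-scale mixed model (random intercept)."""

    def __init__(self, dataset: LongitudinalDataset, inner: str = "emels",
                 quad_points: int = 10, penalize=None):
        if inner not in ("emels", "mem"):
            raise ValueError("inner must be 'emels' or 'mem'")
        self.dataset = dataset
        self.inner = inner
        self.engine = AGHEngine(dataset)
        self.rule = QuadratureRule.gauss_hermite(quad_points, d=3)
        self.P = self.engine.P
        names = dataset.predictor_names
        if penalize is None:
            penalize = np.array([n != INTERCEPT_NAME for n in names])
        self.penalize = np.asarray(penalize, bool)
        self.n_phi_free = 6 if inner == "emels" else 1
        if not dataset.preprocessing_record.get("sds"):
            warnings.warn(
                "predictors do not appear to be standardized; the L1 "
                "penalty is scale-dependent", stacklevel=2)

    # -- likelihood plumbing ----------------------------------------------
    def _init_gamma(self):
        th = initial_theta(self.dataset, 1)
        if self.inner == "emels":
            return np.concatenate([[th.s0, th.r0], th.phi_chol])
        return np.array([th.s0, th.r0, 0.5 * np.log(0.1)])

    def _loglik(self, beta, gamma, adapt=None) -> float:
        if self.inner == "mem":
            phi_tau2 = float(np.exp(2.0 * np.clip(gamma[2], -20, 20)))
            return self.engine.marginal_loglik_linear(
                beta, float(gamma[0]), float(gamma[1]), phi_tau2)
        th = Theta(beta, float(gamma[0]), float(gamma[1]), gamma[2:], k=1)
        if adapt is None:
            adapt = self.engine.adapt(th, self.rule)
        return self.engine.loglik(th, adapt)

    def _adapt(self, beta, gamma, warm=None):
        if self.inner == "mem":
            return None
        th = Theta(beta, float(gamma[0]), float(gamma[1]), gamma[2:], k=1)
        return self.engine.adapt(th, self.rule, warm_modes=warm)

    def _penalty(self, lam, beta) -> float:
        return lam * float(np.sum(np.abs(beta[self.penalize])))

    # -- single-lambda fit -------------------------------------------------
    def fit(self, lam: float, start=None, tol: float = 1e-5,
            max_cycles: int = 40, max_prox: int = 60) -> LassoFit:
        """Block coordinate ascent at one penalty value."""
        if lam < 0:
            raise ValueError("lam must be >= 0")
        if start is None:
            beta = initial_theta(self.dataset, 1).beta
            gamma = self._init_gamma()
        else:
            beta, gamma = start[0].copy(), start[1].copy()
        adapt = self._adapt(beta, gamma)
        pen_obj = self._loglik(beta, gamma, adapt) - self._penalty(lam, beta)
        eta = 1.0
        converged = False
        n_cycles = 0
        for cycle in range(max_cycles):
            # (a) beta block: proximal gradient with backtracking
            ll_beta = lambda b: self._loglik(b, gamma, adapt)
            f_cur = ll_beta(beta)
            for _ in range(max_prox):
                g = central_gradient(ll_beta, beta, h=1e-6)
                accepted = False
                eta_try = min(eta * 4.0, 1e3)
                for _ in range(60):
                    cand = beta + eta_try * g
                    cand = np.where(
                        self.penalize,
                        _soft_threshold(cand, eta_try * lam), cand)
                    f_cand = ll_beta(cand)
                    if (f_cand - lam * np.sum(np.abs(cand[self.penalize]))
                            >= f_cur - lam * np.sum(np.abs(beta[self.penalize]))
                            - 1e-12):
                        accepted = True
                        break
                    eta_try *= 0.5
                if not accepted:
                    break
                eta = eta_try
                delta = np.max(np.abs(cand - beta))
                beta, f_cur = cand, f_cand
                if delta < 1e-7 * (1.0 + np.max(np.abs(beta))):
                    break
            # (b) gamma block: quasi-Newton at fixed beta
            nll = lambda gm: -self._loglik(beta, gm, adapt)
            res = optimize.minimize(
                nll, gamma, jac=lambda gm: central_gradient(nll, gm, h=1e-6),
                method="L-BFGS-B", options={"maxiter": 40, "ftol": 1e-12})
            gamma = res.x
            adapt = self._adapt(beta, gamma,
                                warm=None if adapt is None else adapt.modes)
            pen_new = self._loglik(beta, gamma, adapt) - self._penalty(lam, beta)
            n_cycles = cycle + 1
            if abs(pen_new - pen_obj) < tol * (abs(pen_new) + 1.0):
                pen_obj = pen_new
                converged = True
                break
            pen_obj = pen_new
        ll = self._loglik(beta, gamma, adapt)
        df = int(np.sum(beta != 0.0)) + 2 + self.n_phi_free
        return LassoFit(
            lam=float(lam), beta=beta, beta_names=list(self.dataset.predictor_names),
            gamma=gamma, loglik=ll, penalized_loglik=ll - self._penalty(lam, beta),
            df=df, nobs=self.dataset.n_total, converged=converged,
            n_cycles=n_cycles, inner=self.inner,
        )

    # -- lambda path -------------------------------------------------------
    def fit_path(self, lambdas=None, criterion: str = "bic",
                 tol: float = 1e-5, refit: bool = True) -> "LassoPath":
        """Fit an increasing penalty path with warm starts and select the
        penalty minimizing the chosen information criterion."""
        if lambdas is None:
            lambdas = default_lambda_grid()
        lambdas = np.sort(np.asarray(lambdas, float))
        if lambdas.size == 0:
            raise ValueError("empty lambda grid")
        if criterion not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")
        fits = []
        start = None
        for lam in lambdas:
            f = self.fit(lam, start=start, tol=tol)
            fits.append(f)
            start = (f.beta, f.gamma)
        crit = np.array([getattr(f, criterion) for f in fits])
        sel = int(np.argmin(crit))
        path = LassoPath(lambdas=lambdas, fits=fits, criterion=criterion,
                         selected_index=sel, model=self)
        if refit:
            path.refit = path.refit_selected()
        return path


@dataclass
class LassoPath:
    """A fitted penalty path with the selected model and optional refit."""

    lambdas: np.ndarray
    fits: list
    criterion: str
    selected_index: int
    model: LassoEMELS
    refit: LocationScaleResults | None = None

    @property
    def selected_lambda(self) -> float:
        return float(self.lambdas[self.selected_index])

    @property
    def selected_fit(self) -> LassoFit:
        return self.fits[self.selected_index]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": self.lambdas,
            "loglik": [f.loglik for f in self.fits],
            "df": [f.df for f in self.fits],
            "aic": [f.aic for f in self.fits],
            "bic": [f.bic for f in self.fits],
            "n_nonzero": [f.n_nonzero for f in self.fits],
        })

    def refit_selected(self) -> LocationScaleResults:
        """Unpenalized refit on the selected support; this is the model
        used for prediction (less biased variance components)."""
        f = self.selected_fit
        support = [n for n in f.nonzero if n != INTERCEPT_NAME]
        cols = [INTERCEPT_NAME] + support if INTERCEPT_NAME in \
            f.beta_names else support
        if not cols:
            cols = [INTERCEPT_NAME]
        sub = self.model.dataset.select_predictors(cols)
        if self.model.inner == "emels":
            return EMELS(sub, quad_points=self.model.rule.Q).fit()
        return MixedAR1(sub).fit()


# -- functional wrappers ----------------------------------------------------

def fit_lasso_emels(ds, k: int = 1, lam: float = 0.0, quad_points: int = 10,
                    init=None, tol: float = 1e-5, inner: str = "emels",
                    **kw) -> LassoFit:
    if k != 1:
        raise NotImplementedError("only the random-intercept model (k=1)")
    return LassoEMELS(ds, inner=inner, quad_points=quad_points).fit(
        lam, start=init, tol=tol, **kw)


def lambda_path(ds, k: int = 1, lambdas=None, criterion: str = "bic",
                quad_points: int = 10, inner: str = "emels",
                **kw) -> LassoPath:
    if k != 1:
        raise NotImplementedError("only the random-intercept model (k=1)")
    return LassoEMELS(ds, inner=inner, quad_points=quad_points).fit_path(
        lambdas=lambdas, criterion=criterion, **kw)


def refit_selected(ds, path: LassoPath) -> LocationScaleResults:
    return path.refit_selected()
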