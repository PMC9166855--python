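"""Generators emitting data with exactly the structure the models assume.

All generators are seed-deterministic and return a
:class:`~emels.data.LongitudinalDataset` plus a "truths" record (the
generating parameters and per-person random effects) for recovery tests.

Two scenarios are provided:

* :func:`simulate_emels` -- a linear mean structure with a random
  intercept, person-specific log residual variance and atanh
  autocorrelation, i.e. the model's own generative process.
* :func:`simulate_tree_scenario` -- nine i.i.d. Uniform(0, 10) predictors
  redrawn at every occasion, of which only the first three matter: the
  outcome follows a four-leaf regression tree (means 10/11/12/13 split at
  5 on x1, then x2 or x3) plus a random intercept and person-specific
  AR(1) noise (s0 = -0.67, r0 = 0.26, Phi = diag(1.0, 0.5, 0.5)).
  Defaults: I = 200 persons, T = 51 occasions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import INTERCEPT_NAME, LongitudinalDataset, PersonSeries

__all__ = [
    "SimScenario",
    "simulate_ar1_errors",
    "simulate_emels",
    "simulate_tree_scenario",
    "add_interactions",
]


@dataclass
class SimScenario:
    """Design of a simulation run (persons, occasions, parameters, seed)."""

    I: int
    T: int
    beta: np.ndarray | None = None
    s0: float = 0.0
    r0: float = 0.0
    phi: np.ndarray | None = None
    predictor_law: str = "uniform"   # 'uniform' on [0,10] or 'normal'
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)


def simulate_ar1_errors(sigma2: float, rho: float, T: int, seed=0) -> np.ndarray:
    """Stationary AR(1) Gaussian noise: marginal variance
    sigma2 / (1 - rho**2), lag-1 autocorrelation rho.

    Drawn by the exact stationary recursion (equivalent to one draw from
    N(0, Sigma) with the dense AR(1) covariance).
    """
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if sigma2 <= 0 or T < 1:
        raise ValueError("sigma2 must be > 0 and T >= 1")
    rng = _rng(seed)
    c = sigma2 / (1.0 - rho ** 2)
    z = rng.standard_normal(T)
    e = np.empty(T)
    e[0] = np.sqrt(c) * z[0]
    scale = np.sqrt(c * (1.0 - rho ** 2))
    for t in range(1, T):
        e[t] = rho * e[t - 1] + scale * z[t]
    return e


def _draw_effects(I, phi, rng):
    phi = np.asarray(phi, float)
    w, V = np.linalg.eigh(phi)
    if np.any(w < -1e-10):
        raise ValueError("Phi must be positive semidefinite")
    A = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    return rng.standard_normal((I, phi.shape[0])) @ A.T


def _draw_predictors(I, T, p, law, rng):
    if law == "uniform":
        return rng.uniform(0.0, 10.0, size=(I, T, p))
    if law == "normal":
        return rng.standard_normal((I, T, p))
    raise ValueError(f"unknown predictor law {law!r}")


def simulate_emels(
    I: int,
    T: int,
    beta,
    s0: float,
    r0: float,
    phi,
    seed=0,
    predictor_law: str = "uniform",
    predictor_names=None,
):
    """Simulate from the linear location-scale model itself.

    ``beta`` includes the intercept; ``phi`` is the 3x3 covariance of
    (tau_i, omega_i, iota_i).  Returns (dataset, truths) where truths holds
    the generating parameters and the drawn per-person effects.
    """
    rng = _rng(seed)
    beta = np.asarray(beta, float)
    p = beta.size - 1
    v = _draw_effects(I, phi, rng)
    Xp = _draw_predictors(I, T, p, predictor_law, rng)
    names = predictor_names or [f"x{j+1}" for j in range(p)]
    series = []
    for i in range(I):
        tau, omega, iota = v[i]
        sig2 = float(np.exp(np.clip(s0 + omega, -30, 30)))
        rho = float(np.tanh(r0 + iota))
        X = np.column_stack([np.ones(T), Xp[i]])
        eps = simulate_ar1_errors(sig2, rho, T, rng)
        y = X @ beta + tau + eps
        series.append(PersonSeries(i + 1, np.arange(1, T + 1), y, X,
                                   np.ones((T, 1))))
    ds = LongitudinalDataset(series, [INTERCEPT_NAME] + list(names))
    truths = {"beta": beta, "s0": s0, "r0": r0,
              "phi": np.asarray(phi, float), "v": v}
    return ds, truths


TREE_LEAF_MEANS = (10.0, 11.0, 12.0, 13.0)


def _tree_mean(x1, x2, x3):
    """Four-leaf rule: split on x1 at 5, then x2 (left) or x3 (right)."""
    out = np.where(
        x1 <= 5.0,
        np.where(x2 <= 5.0, TREE_LEAF_MEANS[0], TREE_LEAF_MEANS[1]),
        np.where(x3 <= 5.0, TREE_LEAF_MEANS[2], TREE_LEAF_MEANS[3]),
    )
    leaf = np.where(
        x1 <= 5.0,
        np.where(x2 <= 5.0, 0, 1),
        np.where(x3 <= 5.0, 2, 3),
    )
    return out, leaf


def simulate_tree_scenario(
    I: int = 200,
    T: int = 51,
    seed=0,
    s0: float = -0.67,
    r0: float = 0.26,
    phi_diag=(1.0, 0.5, 0.5),
):
    """The piecewise-constant benchmark scenario (see module docstring).

    Nine observation-level Uniform(0, 10) predictors; only x1, x2, x3 enter
    the outcome through the four-leaf rule; random effects uncorrelated
    with variances ``phi_diag``.  Returns (dataset, truths) with the leaf
    membership of every row in ``truths['leaf']``.
    """
    rng = _rng(seed)
    phi = np.diag(np.asarray(phi_diag, float))
    v = _draw_effects(I, phi, rng)
    Xp = _draw_predictors(I, T, 9, "uniform", rng)
    series = []
    leaves = []
    for i in range(I):
        tau, omega, iota = v[i]
        sig2 = float(np.exp(np.clip(s0 + omega, -30, 30)))
        rho = float(np.tanh(r0 + iota))
        mu, leaf = _tree_mean(Xp[i, :, 0], Xp[i, :, 1], Xp[i, :, 2])
        eps = simulate_ar1_errors(sig2, rho, T, rng)
        y = mu + tau + eps
        X = np.column_stack([np.ones(T), Xp[i]])
        series.append(PersonSeries(i + 1, np.arange(1, T + 1), y, X,
                                   np.ones((T, 1))))
        leaves.append(leaf)
    names = [INTERCEPT_NAME] + [f"x{j+1}" for j in range(9)]
    ds = LongitudinalDataset(series, names)
    truths = {"s0": s0, "r0": r0, "phi": phi, "v": v,
              "leaf": np.concatenate(leaves),
              "leaf_means": np.array(TREE_LEAF_MEANS)}
    return ds, truths


def add_interactions(ds: LongitudinalDataset, pairs) -> LongitudinalDataset:
    """Append product columns (named 'a:b') for each (a, b) predictor pair.

    Second-order terms like x1:x2 let a linear mean structure represent
    the interactions that a tree encodes through nested splits.
    """
    names = list(ds.predictor_names)
    new_names = names + [f"{a}:{b}" for a, b in pairs]
    series = []
    for s in ds.series:
        cols = [s.X[:, names.index(a)] * s.X[:, names.index(b)]
                for a, b in pairs]
        X = np.column_stack([s.X] + cols)
        series.append(PersonSeries(s.person_id, s.times, s.y, X, s.Z))
    return LongitudinalDataset(series, new_names,
                               dict(ds.preprocessing_record))
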