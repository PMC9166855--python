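"""Person-specific AR(1) residual covariance and the location-scale links.

The residual process of person *i* is stationary lag-1 autoregressive with

    sigma2_i = exp(s0 + omega_i),    rho_i = tanh(r0 + iota_i),

and covariance matrix ``Sigma_i = sigma2_i / (1 - rho_i**2) * R`` where
``R[j, k] = rho_i ** |j - k|``.  The exp link keeps the variance positive and
the tanh link keeps the autocorrelation inside (-1, 1).

Because ``R^{-1}`` is tridiagonal, log-determinants and quadratic forms are
available in O(T) without ever forming the dense matrix:

    Sigma^{-1}      = M / sigma2
    M               = I + rho**2 * E - rho * N
    log det Sigma   = T * log(sigma2) - log(1 - rho**2)

with E the diagonal indicator of interior occasions and N the adjacency
matrix of the path graph (valid for T >= 2; T = 1 is a scalar special case).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "person_sigma2",
    "person_rho",
    "ar1_covariance",
    "ar1_logdet_and_solve",
]

# Exponent clip bound for exp(s0 + omega): 3-D quadrature tail nodes can be
# extreme, and exp(>30) overflows the likelihood for nothing.
EXP_CLIP = 30.0


def person_sigma2(s0, omega):
    """Residual variance exp(s0 + omega), overflow-guarded."""
    return np.exp(np.clip(np.asarray(s0, float) + np.asarray(omega, float),
                          -EXP_CLIP, EXP_CLIP))


def person_rho(r0, iota):
    """Autocorrelation tanh(r0 + iota), strictly inside (-1, 1)."""
    return np.tanh(np.asarray(r0, float) + np.asarray(iota, float))


def _check(sigma2: float, rho: float, T: int) -> None:
    if not sigma2 > 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")


def ar1_covariance(sigma2: float, rho: float, T: int) -> np.ndarray:
    """Dense stationary AR(1) covariance, entry (j,k) = c * rho**|j-k|
    with c = sigma2 / (1 - rho**2)."""
    _check(sigma2, rho, T)
    idx = np.arange(T)
    return sigma2 / (1.0 - rho ** 2) * rho ** np.abs(idx[:, None] - idx[None, :])


def ar1_precision_apply(rho: float, v: np.ndarray) -> np.ndarray:
    """Apply M = (1 - rho**2) * R^{-1} to the columns of v in O(T)."""
    v = np.asarray(v, float)
    T = v.shape[0]
    if T == 1:
        return (1.0 - rho ** 2) * v
    out = v.copy()
    out[1:-1] *= 1.0 + rho ** 2
    out[:-1] -= rho * v[1:]
    out[1:] -= rho * v[:-1]
    return out


def ar1_logdet_and_solve(sigma2: float, rho: float, T: int, rhs):
    """Log-determinant of Sigma and Sigma^{-1} @ rhs, both in O(T).

    Agrees with a dense Cholesky factorization to machine precision; used by
    the likelihood so that no T x T matrix is ever materialized.
    """
    _check(sigma2, rho, T)
    rhs = np.asarray(rhs, float)
    if rhs.shape[0] != T:
        raise ValueError("rhs has wrong leading dimension")
    logdet = T * np.log(sigma2) - np.log1p(-rho ** 2)
    solved = ar1_precision_apply(rho, rhs) / sigma2 if T > 1 else \
        (1.0 - rho ** 2) * rhs / sigma2
    return logdet, solved


def ar1_quadform(sigma2: float, rho: float, r: np.ndarray) -> float:
    """r' Sigma^{-1} r in O(T)."""
    _, s = ar1_logdet_and_solve(sigma2, rho, r.shape[0], r)
    return float(r @ s)


def mvn_logpdf_chol(v: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Log-density of N(0, L L') evaluated at the rows of v (batched)."""
    v2 = np.atleast_2d(v)
    w = solve_triangular(L, v2.T, lower=True)
    d = L.shape[0]
    out = (
        -0.5 * d * np.log(2 * np.pi)
        - np.sum(np.log(np.diag(L)))
        - 0.5 * np.sum(w * w, axis=0)
    )
    return out if np.ndim(v) > 1 else float(out[0])
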