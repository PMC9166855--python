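"""Parameter vector for the extended location-scale mixed model.

The full parameter set is theta = (beta, s0, r0, Phi) where Phi is the
(k+2) x (k+2) covariance matrix of the joint random effect
v_i = (b_i, omega_i, iota_i).  For unconstrained optimization Phi is carried
as a log-Cholesky vector: the lower triangle of its Cholesky factor, row by
row, with the diagonal on the log scale.  This guarantees positive
definiteness for every real-valued parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Theta", "phi_from_chol", "chol_from_phi"]

_LOGDIAG_CLIP = 20.0


def _tril_index(d: int):
    return np.tril_indices(d)


def phi_chol_factor(phi_chol: np.ndarray, d: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from the log-Cholesky vector."""
    L = np.zeros((d, d))
    L[_tril_index(d)] = phi_chol
    diag = np.clip(np.diag(L), -_LOGDIAG_CLIP, _LOGDIAG_CLIP)
    L[np.diag_indices(d)] = np.exp(diag)
    return L


def phi_from_chol(phi_chol: np.ndarray, d: int) -> np.ndarray:
    L = phi_chol_factor(phi_chol, d)
    return L @ L.T


def chol_from_phi(phi: np.ndarray) -> np.ndarray:
    """Inverse map; requires a positive-definite Phi."""
    L = np.linalg.cholesky(phi)
    out = L.copy()
    out[np.diag_indices(phi.shape[0])] = np.log(np.diag(L))
    return out[_tril_index(phi.shape[0])]


@dataclass
class Theta:
    """Full model parameters on the unconstrained scale.

    beta : fixed effects (length p+1, or G for a tree dummy design)
    s0   : mean log residual variance
    r0   : mean atanh autocorrelation
    phi_chol : log-Cholesky vector of Phi, length (k+2)(k+3)/2
    k    : number of mean-structure random effects (1 = random intercept)
    """

    beta: np.ndarray
    s0: float
    r0: float
    phi_chol: np.ndarray
    k: int = 1

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        self.phi_chol = np.atleast_1d(np.asarray(self.phi_chol, float))
        d = self.k + 2
        if self.phi_chol.shape[0] != d * (d + 1) // 2:
            raise ValueError(
                f"phi_chol must have length {d * (d + 1) // 2} for k={self.k}"
            )

    @property
    def d(self) -> int:
        """Dimension of the joint random effect (k + 2)."""
        return self.k + 2

    @property
    def phi(self) -> np.ndarray:
        return phi_from_chol(self.phi_chol, self.d)

    @property
    def phi_factor(self) -> np.ndarray:
        return phi_chol_factor(self.phi_chol, self.d)

    @classmethod
    def from_phi(cls, beta, s0, r0, phi, k=1) -> "Theta":
        return cls(np.asarray(beta, float), float(s0), float(r0),
                   chol_from_phi(np.asarray(phi, float)), k)

    # -- flat vector interface for optimizers ------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.beta, [self.s0, self.r0], self.phi_chol])

    @classmethod
    def from_vector(cls, x: np.ndarray, n_beta: int, k: int = 1) -> "Theta":
        x = np.asarray(x, float)
        return cls(x[:n_beta], float(x[n_beta]), float(x[n_beta + 1]),
                   x[n_beta + 2:], k)

    @property
    def n_free(self) -> int:
        return self.beta.shape[0] + 2 + self.phi_chol.shape[0]

    def copy(self) -> "Theta":
        return Theta(self.beta.copy(), self.s0, self.r0,
                     self.phi_chol.copy(), self.k)
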