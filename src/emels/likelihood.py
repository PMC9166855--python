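"""Marginal log-likelihood of the location-scale mixed model via adaptive
Gauss-Hermite quadrature (AGH).

Conditional on the joint random effect v_i = (b_i, omega_i, iota_i), the
outcome vector of person *i* is multivariate normal with mean
``X_i beta + Z_i b_i`` and stationary AR(1) covariance built from
``sigma2_i = exp(s0 + omega_i)`` and ``rho_i = tanh(r0 + iota_i)``.  The
marginal likelihood integrates this density against the N(0, Phi) prior of
v_i; the integral has no closed form and is approximated with a tensor
product Gauss-Hermite rule whose nodes are recentered at each person's
posterior mode and rescaled by the Cholesky factor of the inverse curvature
there ("adaptive" quadrature).

The module contains two layers:

* :class:`AGHEngine` -- a vectorized engine for the random-intercept case
  (k = 1, Z a column of ones).  All persons and all quadrature nodes are
  evaluated simultaneously from six per-person sufficient statistics of the
  residual vector, which makes one likelihood evaluation O(n_total) plus
  O(I * Q^3) node arithmetic.  Every fit in the package runs through it.
* module-level operations (`conditional_loglik`, `person_marginal_loglik`,
  `total_loglik`, `loglik_gradient`) -- the reference, per-person API; these
  accept a general Z for the conditional density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .ar1 import EXP_CLIP, ar1_logdet_and_solve, mvn_logpdf_chol
from .data import LongitudinalDataset, PersonSeries
from .numdiff import central_gradient
from .params import Theta

__all__ = [
    "QuadratureRule",
    "AGHEngine",
    "conditional_loglik",
    "person_marginal_loglik",
    "total_loglik",
    "loglik_gradient",
]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class QuadratureRule:
    """Tensor-product Gauss-Hermite rule over d dimensions.

    ``nodes`` is (Q^d, d); ``log_weights`` already includes the exp(|u|^2)
    correction so that  integral f(u) du ~= sum_q exp(log_weights_q) f(u_q).
    """

    Q: int
    d: int
    nodes: np.ndarray
    log_weights: np.ndarray

    @classmethod
    def gauss_hermite(cls, Q: int, d: int = 3) -> "QuadratureRule":
        if Q < 1:
            raise ValueError("Q must be >= 1")
        u, w = np.polynomial.hermite.hermgauss(Q)
        grids = np.meshgrid(*([u] * d), indexing="ij")
        U = np.column_stack([g.ravel() for g in grids])
        logw = np.zeros(Q ** d)
        for j in range(d):
            logw += np.log(w)[
                np.meshgrid(*([np.arange(Q)] * d), indexing="ij")[j].ravel()
            ]
        logw += np.sum(U ** 2, axis=1)
        return cls(Q=Q, d=d, nodes=U, log_weights=logw)


@dataclass
class Adaptation:
    """Per-person quadrature adaptation: posterior modes and curvature."""

    modes: np.ndarray        # (I, d) posterior modes in whitened coordinates
    chol: np.ndarray         # (I, d, d) v-space scale C_i, C_i C_i' = cov
    logdet_chol: np.ndarray  # (I,)
    v_nodes: np.ndarray      # (I, N, d) shifted/scaled nodes
    log_w: np.ndarray        # (I, N) per-person node log-weights


def _batch_pd_solve(H: np.ndarray, g: np.ndarray, floor: float = 1e-8,
                    max_step: float = 4.0):
    """Modified-Newton direction for batches of symmetric H.

    Negative or tiny eigenvalues are replaced by their absolute value
    (saddle-free Newton) with a relative floor, and the step is capped in
    norm so that backtracking always operates on a sane candidate.
    """
    w, V = np.linalg.eigh(H)
    w = np.abs(w)
    w = np.maximum(w, np.maximum(floor, 1e-6 * w.max(axis=1, keepdims=True)))
    coef = np.einsum("iqd,iq->id", V, g) / w
    x = np.einsum("idq,iq->id", V, coef)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    scale = np.where(norms > max_step,
                     max_step / np.maximum(norms, 1e-300), 1.0)
    return x * scale, w, V


class AGHEngine:
    """Vectorized likelihood engine for the random-intercept model (k=1)."""

    def __init__(self, dataset: LongitudinalDataset):
        if dataset.n_persons == 0:
            raise ValueError("empty dataset")
        for s in dataset.series:
            if s.Z.shape[1] != 1 or not np.allclose(s.Z, 1.0):
                raise NotImplementedError(
                    "the AGH engine supports the random-intercept model "
                    "(k=1, Z a column of ones)"
                )
        self.dataset = dataset
        self.I = dataset.n_persons
        self.T = np.array([s.n_obs for s in dataset.series], dtype=float)
        self.y = np.concatenate([s.y for s in dataset.series])
        self.X = np.vstack([s.X for s in dataset.series])
        self.P = self.X.shape[1]
        lengths = np.array([s.n_obs for s in dataset.series])
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])[:-1]
        self.first_idx = self.offsets
        self.last_idx = self.offsets + lengths - 1
        # mask selecting rows t = 1..T-1 within each person (for lag products)
        keep = np.ones(self.y.shape[0], dtype=bool)
        keep[self.last_idx] = False
        self._lag_keep = keep
        self._seg = self.offsets  # reduceat segment starts

    # -- residual sufficient statistics -----------------------------------
    def resid_stats(self, beta: np.ndarray):
        """Per-person sufficient statistics of r = y - X beta.

        Returns arrays (S1, S2, S3, s, s_mid, u3, first, last) of shape (I,)
        where S1 = sum r^2, S2 = interior sum of r^2, S3 = sum r_t r_{t+1},
        s = sum r, s_mid = interior sum of r, u3 = 2 s - r_1 - r_T.
        """
        r = self.y - self.X @ beta
        r2 = r * r
        S1 = np.add.reduceat(r2, self._seg)
        s = np.add.reduceat(r, self._seg)
        f = r[self.first_idx]
        l = r[self.last_idx]
        S2 = S1 - f * f - l * l
        s_mid = s - f - l
        lag = r[self._lag_keep] * np.append(r[1:], 0.0)[self._lag_keep]
        # reduceat over possibly-empty segments needs segment starts mapped
        S3 = self._reduce_lagged(lag)
        u3 = 2.0 * s - f - l
        return S1, S2, S3, s, s_mid, u3

    def _reduce_lagged(self, lag: np.ndarray) -> np.ndarray:
        lengths = (self.T - 1).astype(int)
        out = np.zeros(self.I)
        if lag.size == 0:
            return out
        starts = np.concatenate([[0], np.cumsum(lengths)])[:-1]
        nonempty = lengths > 0
        sums = np.add.reduceat(lag, starts[nonempty])
        out[nonempty] = sums
        return out

    # -- conditional log-likelihood over node batches ----------------------
    def cond_logliks(self, stats, b, omega, iota, s0: float, r0: float):
        """Conditional log density for each person at each node.

        ``b, omega, iota`` broadcast against shape (I, N); stats come from
        :meth:`resid_stats`.  Returns an (I, N) array.
        """
        S1, S2, S3, s, s_mid, u3 = stats
        T = self.T[:, None]
        S1 = S1[:, None]
        S2 = S2[:, None]
        S3 = S3[:, None]
        s = s[:, None]
        s_mid = s_mid[:, None]
        u3 = u3[:, None]
        log_sig2 = np.clip(s0 + omega, -EXP_CLIP, EXP_CLIP)
        sig2 = np.exp(log_sig2)
        # tanh rounds to +-1.0 in float64 beyond |x| ~ 19; keep |rho| < 1
        rho = np.clip(np.tanh(r0 + iota), -1.0 + 1e-12, 1.0 - 1e-12)
        b2 = b * b
        A = S1 - 2.0 * b * s + T * b2
        B = S2 - 2.0 * b * s_mid + (T - 2.0) * b2
        C = S3 - b * u3 + (T - 1.0) * b2
        quad = (A + rho * rho * B - 2.0 * rho * C) / sig2
        if np.any(self.T == 1):
            quad1 = A * (1.0 - rho * rho) / sig2
            quad = np.where(T == 1, quad1, quad)
        return (
            -0.5 * T * LOG2PI
            - 0.5 * (T * log_sig2 - np.log1p(-rho * rho))
            - 0.5 * quad
        )

    def _prior_logpdf(self, v: np.ndarray, theta: Theta) -> np.ndarray:
        """N(0, Phi) log density for v of shape (..., d)."""
        L = theta.phi_factor
        flat = v.reshape(-1, theta.d)
        w = solve_triangular(L, flat.T, lower=True)
        out = (
            -0.5 * theta.d * LOG2PI
            - np.sum(np.log(np.diag(L)))
            - 0.5 * np.sum(w * w, axis=0)
        )
        return out.reshape(v.shape[:-1])

    def joint_logpdf(self, theta: Theta, stats, v: np.ndarray) -> np.ndarray:
        """log f(y_i | v_i) + log f(v_i | Phi) for one v per person, (I, d)."""
        cond = self.cond_logliks(
            stats, v[:, None, 0], v[:, None, 1], v[:, None, 2],
            theta.s0, theta.r0,
        )[:, 0]
        return cond + self._prior_logpdf(v, theta)

    def _joint_whitened(self, theta: Theta, stats, u: np.ndarray,
                        L: np.ndarray) -> np.ndarray:
        """Joint log density in whitened coordinates v = L u (up to the
        constant -log|L|): the prior becomes standard normal, which keeps
        finite differences well-conditioned for any Phi."""
        v = u @ L.T
        cond = self.cond_logliks(
            stats, v[:, None, 0], v[:, None, 1], v[:, None, 2],
            theta.s0, theta.r0,
        )[:, 0]
        return cond - 0.5 * np.sum(u * u, axis=1)

    # -- adaptation --------------------------------------------------------
    def find_modes(self, theta: Theta, stats, u0=None, max_iter=60,
                   tol=1e-9, fd_h=1e-4, hess_h=3e-3):
        """Batched damped-Newton search for each person's posterior mode in
        whitened coordinates.

        Returns (modes_u, neg_hessians_u): the mode and the central
        finite-difference curvature of the negative whitened joint density.
        """
        d = theta.d
        L = theta.phi_factor
        v = np.zeros((self.I, d)) if u0 is None else u0.copy()
        joint = lambda uu: self._joint_whitened(theta, stats, uu, L)
        fval = joint(v)
        for _ in range(max_iter):
            g, H = self._grad_hess(joint, v, fd_h)
            gnorm = np.max(np.abs(g), axis=1)
            if np.max(gnorm) < tol:
                break
            step, _, _ = _batch_pd_solve(-H, g)
            alpha = np.ones(self.I)
            improved = np.zeros(self.I, dtype=bool)
            best_v = v.copy()
            best_f = fval.copy()
            for half in range(40):
                cand = v + alpha[:, None] * step
                fc = joint(cand)
                better = fc > best_f
                best_v[better] = cand[better]
                best_f[better] = fc[better]
                improved |= better
                if improved.all():
                    break
                alpha = np.where(improved, alpha, alpha * 0.5)
            stuck = ~improved & (np.max(np.abs(g), axis=1) > tol)
            if stuck.any():
                # fall back to a damped gradient step for pathological rows
                gstep = g / (1.0 + np.linalg.norm(g, axis=1, keepdims=True))
                alpha = np.ones(self.I)
                for half in range(40):
                    cand = v + alpha[:, None] * gstep
                    fc = joint(cand)
                    better = stuck & (fc > best_f)
                    best_v[better] = cand[better]
                    best_f[better] = fc[better]
                    improved |= better
                    alpha *= 0.5
            if not improved.any():
                break
            v, fval = best_v, best_f
        # final curvature with a larger step: the second difference of a
        # ~1e1-magnitude density loses ~7 digits to cancellation at h=1e-4,
        # and that noise would leak into the quadrature scale
        _, H = self._grad_hess(joint, v, hess_h)
        return v, -H

    def _grad_hess(self, f, v, h):
        I, d = v.shape
        f0 = f(v)
        g = np.empty((I, d))
        H = np.empty((I, d, d))
        fp = np.empty((d, I))
        fm = np.empty((d, I))
        for j in range(d):
            e = np.zeros(d)
            e[j] = h
            fp[j] = f(v + e)
            fm[j] = f(v - e)
            g[:, j] = (fp[j] - fm[j]) / (2 * h)
            H[:, j, j] = (fp[j] - 2 * f0 + fm[j]) / h ** 2
        for a in range(d):
            for bidx in range(a + 1, d):
                ea = np.zeros(d)
                eb = np.zeros(d)
                ea[a] = h
                eb[bidx] = h
                m = (
                    f(v + ea + eb) - f(v + ea - eb)
                    - f(v - ea + eb) + f(v - ea - eb)
                ) / (4 * h * h)
                H[:, a, bidx] = m
                H[:, bidx, a] = m
        return g, H

    def adapt(self, theta: Theta, rule: QuadratureRule,
              warm_modes=None) -> Adaptation:
        """Recenter and rescale the quadrature at each posterior mode.

        The mode search and curvature run in whitened coordinates u
        (v = L u with L the Cholesky factor of Phi); the returned nodes and
        weights live in v space.
        """
        stats = self.resid_stats(theta.beta)
        L = theta.phi_factor
        modes_u, negH_u = self.find_modes(theta, stats, u0=warm_modes)
        w, V = np.linalg.eigh(negH_u)
        w = np.maximum(w, 1e-8)
        # C_u = V diag(1/sqrt(w)) V'  gives C_u C_u' = (negH_u)^{-1}
        C_u = np.einsum("idq,iq,ijq->idj", V, 1.0 / np.sqrt(w), V)
        C = np.einsum("pq,iqj->ipj", L, C_u)   # v-space scale: L C_u
        logdetC = (np.sum(np.log(np.diag(L)))
                   - 0.5 * np.sum(np.log(w), axis=1))
        v_modes = modes_u @ L.T
        v_nodes = v_modes[:, None, :] + np.sqrt(2.0) * np.einsum(
            "ijq,nq->inj", C, rule.nodes
        )
        log_w = (
            rule.log_weights[None, :]
            + 0.5 * theta.d * np.log(2.0)
            + logdetC[:, None]
        )
        return Adaptation(modes_u, C, logdetC, v_nodes, log_w)

    # -- objective ---------------------------------------------------------
    def person_logliks(self, theta: Theta, adaptation: Adaptation):
        stats = self.resid_stats(theta.beta)
        v = adaptation.v_nodes
        cond = self.cond_logliks(
            stats, v[:, :, 0], v[:, :, 1], v[:, :, 2], theta.s0, theta.r0
        )
        prior = self._prior_logpdf(v, theta)
        vals = adaptation.log_w + cond + prior
        out = logsumexp(vals, axis=1)
        if not np.all(np.isfinite(out)):
            bad = int(np.flatnonzero(~np.isfinite(out))[0])
            pid = self.dataset.series[bad].person_id
            raise FloatingPointError(
                f"non-finite marginal likelihood for person {pid!r}"
            )
        return out

    def loglik(self, theta: Theta, adaptation: Adaptation) -> float:
        return float(np.sum(self.person_logliks(theta, adaptation)))

    # -- empirical-Bayes posterior means -----------------------------------
    def eb_means(self, theta: Theta, adaptation: Adaptation) -> np.ndarray:
        """Posterior mean of v_i per person via the adapted rule, (I, d)."""
        stats = self.resid_stats(theta.beta)
        v = adaptation.v_nodes
        cond = self.cond_logliks(
            stats, v[:, :, 0], v[:, :, 1], v[:, :, 2], theta.s0, theta.r0
        )
        logpost = adaptation.log_w + cond + self._prior_logpdf(v, theta)
        logpost = logpost - logsumexp(logpost, axis=1, keepdims=True)
        w = np.exp(logpost)
        return np.einsum("in,ind->id", w, v)

    # -- linear-model marginal likelihood (omega, iota variances zero) -----
    def marginal_loglik_linear(self, beta, s0, r0, phi_tau2) -> float:
        """Closed-form marginal normal log-likelihood of the AR(1) linear
        mixed model with V_i = phi_tau2 * 11' + Sigma_i, via Woodbury."""
        stats = self.resid_stats(np.asarray(beta, float))
        S1, S2, S3, s, s_mid, u3 = stats
        T = self.T
        sig2 = np.exp(np.clip(s0, -EXP_CLIP, EXP_CLIP))
        rho = float(np.clip(np.tanh(r0), -1.0 + 1e-12, 1.0 - 1e-12))
        q11 = (T + rho * rho * (T - 2.0) - 2.0 * rho * (T - 1.0)) / sig2
        qr1 = (s + rho * rho * s_mid - rho * u3) / sig2
        qrr = (S1 + rho * rho * S2 - 2.0 * rho * S3) / sig2
        one = T == 1
        if np.any(one):
            q11 = np.where(one, (1.0 - rho * rho) / sig2, q11)
            qr1 = np.where(one, s * (1.0 - rho * rho) / sig2, qr1)
            qrr = np.where(one, S1 * (1.0 - rho * rho) / sig2, qrr)
        denom = 1.0 + phi_tau2 * q11
        logdet = T * np.log(sig2) - np.log1p(-rho * rho) + np.log(denom)
        quad = qrr - phi_tau2 * qr1 * qr1 / denom
        ll = -0.5 * T * LOG2PI - 0.5 * logdet - 0.5 * quad
        return float(np.sum(ll))

    def eb_intercepts_linear(self, beta, s0, r0, phi_tau2) -> np.ndarray:
        """Closed-form random-intercept estimates Phi Z' V^{-1} (y - X beta)
        for the linear AR(1) model (one scalar per person)."""
        stats = self.resid_stats(np.asarray(beta, float))
        _, _, _, s, s_mid, u3 = stats
        T = self.T
        sig2 = np.exp(np.clip(s0, -EXP_CLIP, EXP_CLIP))
        rho = np.tanh(r0)
        q11 = (T + rho * rho * (T - 2.0) - 2.0 * rho * (T - 1.0)) / sig2
        qr1 = (s + rho * rho * s_mid - rho * u3) / sig2
        one = T == 1
        if np.any(one):
            q11 = np.where(one, (1.0 - rho * rho) / sig2, q11)
            qr1 = np.where(one, s * (1.0 - rho * rho) / sig2, qr1)
        return phi_tau2 * qr1 / (1.0 + phi_tau2 * q11)


# ---------------------------------------------------------------------------
# reference per-person operations (general Z in the conditional density)
# ---------------------------------------------------------------------------

def conditional_loglik(series: PersonSeries, v, theta: Theta) -> float:
    """Log density of y_i given the random effects v = (b, omega, iota)."""
    v = np.atleast_1d(np.asarray(v, float))
    k = series.Z.shape[1]
    b, omega, iota = v[:k], v[k], v[k + 1]
    mean = series.X @ theta.beta + series.Z @ b
    r = series.y - mean
    sig2 = float(np.exp(np.clip(theta.s0 + omega, -EXP_CLIP, EXP_CLIP)))
    rho = float(np.tanh(theta.r0 + iota))
    logdet, solved = ar1_logdet_and_solve(sig2, rho, series.n_obs, r)
    return float(-0.5 * series.n_obs * LOG2PI - 0.5 * logdet
                 - 0.5 * (r @ solved))


def _single_engine(series: PersonSeries) -> AGHEngine:
    return AGHEngine(
        LongitudinalDataset([series], [f"x{j}" for j in range(series.X.shape[1])])
    )


def person_marginal_loglik(series: PersonSeries, theta: Theta,
                           rule: QuadratureRule) -> float:
    """AGH approximation of one person's marginal log-likelihood."""
    eng = _single_engine(series)
    return eng.loglik(theta, eng.adapt(theta, rule))


def total_loglik(ds: LongitudinalDataset, theta: Theta,
                 rule: QuadratureRule) -> float:
    """AGH marginal log-likelihood of the whole sample (sum over persons)."""
    eng = AGHEngine(ds)
    return eng.loglik(theta, eng.adapt(theta, rule))


def loglik_gradient(ds: LongitudinalDataset, theta: Theta,
                    rule: QuadratureRule, h: float = 1e-5) -> np.ndarray:
    """Gradient of the marginal log-likelihood over theta's unconstrained
    coordinates (central finite differences of :func:`total_loglik`)."""
    eng = AGHEngine(ds)
    n_beta = theta.beta.shape[0]

    def f(x):
        th = Theta.from_vector(x, n_beta, theta.k)
        return eng.loglik(th, eng.adapt(th, rule))

    return central_gradient(f, theta.to_vector(), h=h)
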