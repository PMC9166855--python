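"""Central finite-difference derivatives used for gradients, Hessians and
standard errors.  Steps are relative to the coordinate magnitude."""

from __future__ import annotations

import numpy as np

__all__ = ["central_gradient", "central_hessian"]


def _steps(x: np.ndarray, h: float) -> np.ndarray:
    return h * (1.0 + np.abs(x))


def central_gradient(f, x, h: float = 1e-5) -> np.ndarray:
    """Central-difference gradient, O(h^2) accurate, 2n evaluations."""
    x = np.asarray(x, float)
    hs = _steps(x, h)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = hs[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * hs[i])
    return g


def central_hessian(f, x, h: float = 5e-4) -> np.ndarray:
    """Central-difference Hessian (symmetric), O(h^2) accurate."""
    x = np.asarray(x, float)
    n = x.size
    hs = _steps(x, h)
    H = np.empty((n, n))
    f0 = f(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = hs[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / hs[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = hs[i]
            ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hs[i] * hs[j])
    return H
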