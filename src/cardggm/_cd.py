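"""Numba kernels for the block coordinate-descent sweeps of graphical lasso.

Each call to :func:`glasso_sweep` performs one full pass over the p columns,
updating the working covariance ``Sigma`` and precision ``Omega`` in place.
Zeros in the precision matrix are exact: they come out of the inner
soft-thresholding step, never from rounding.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso_sweep", "soft_threshold_scalar"]


@njit(cache=True)
def soft_threshold_scalar(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def _lasso_cd(W11, s12, lam12, beta, inner_tol, inner_max_iter):
    """Coordinate descent for 0.5*b'W11 b - b's12 + sum lam12|b|, warm-started."""
    m = beta.shape[0]
    for _ in range(inner_max_iter):
        max_delta = 0.0
        for k in range(m):
            # residual excluding coordinate k
            r = s12[k]
            for l in range(m):
                if l != k:
                    r -= W11[k, l] * beta[l]
            new = soft_threshold_scalar(r, lam12[k]) / W11[k, k]
            d = abs(new - beta[k])
            if d > max_delta:
                max_delta = d
            beta[k] = new
        if max_delta < inner_tol:
            break
    return beta


@njit(cache=True)
def glasso_sweep(S, Lam, Sigma, Omega, inner_tol, inner_max_iter):
    """One full column sweep of the graphical lasso block update.

    For each column j the off-diagonal block problem is the lasso
    0.5*b'Sigma11 b - b's_j + sum_k lam_jk |b_k|; afterwards
    sigma_j = Sigma11 @ b, omega_jj = 1/(sigma_jj - sigma_j'b),
    omega_j = -b * omega_jj.  The diagonal of Sigma is fixed at
    S_jj + lam_jj from initialization.
    """
    p = S.shape[0]
    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    lam12 = np.empty(p - 1)
    beta = np.empty(p - 1)
    for j in range(p):
        # gather the (p-1) x (p-1) block excluding row/column j
        a = 0
        for r in range(p):
            if r == j:
                continue
            b = 0
            for c in range(p):
                if c == j:
                    continue
                W11[a, b] = Sigma[r, c]
                b += 1
            s12[a] = S[r, j]
            lam12[a] = Lam[r, j]
            # warm start from the current precision column
            beta[a] = -Omega[r, j] / Omega[j, j]
            a += 1
        _lasso_cd(W11, s12, lam12, beta, inner_tol, inner_max_iter)
        # scatter back: sigma_j = W11 @ beta
        a = 0
        dot_sb = 0.0
        for r in range(p):
            if r == j:
                continue
            sig = 0.0
            for b in range(p - 1):
                sig += W11[a, b] * beta[b]
            Sigma[r, j] = sig
            Sigma[j, r] = sig
            dot_sb += sig * beta[a]
            a += 1
        ojj = 1.0 / (Sigma[j, j] - dot_sb)
        Omega[j, j] = ojj
        a = 0
        for r in range(p):
            if r == j:
                continue
            val = -beta[a] * ojj
            Omega[r, j] = val
            Omega[j, r] = val
            a += 1
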