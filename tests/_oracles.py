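"""Independent oracles used by the test suite.

These deliberately use different algorithm families from the package:
a proximal-gradient (ISTA) solver for the l1-penalized log-determinant
objective, and a support-constrained maximum-likelihood refit via
quasi-Newton optimization over the free entries.  Neither shares code with
the block coordinate-descent / DC implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def prox_grad_glasso(
    S: np.ndarray,
    Lam: np.ndarray | float,
    *,
    max_iter: int = 20000,
    tol: float = 1e-10,
) -> np.ndarray:
    """ISTA with backtracking for min -logdet(O) + tr(OS) + sum Lam|O|."""
    S = np.asarray(S, float)
    p = S.shape[0]
    if np.isscalar(Lam):
        Lam = np.full((p, p), float(Lam))
    Omega = np.linalg.inv(S + np.diag(np.diag(Lam)))
    step = 1.0

    def smooth(O):
        sign, ld = np.linalg.slogdet(O)
        if sign <= 0:
            return np.inf
        return -ld + np.sum(O * S)

    f = smooth(Omega)
    for _ in range(max_iter):
        G = S - np.linalg.inv(Omega)
        while True:
            Z = Omega - step * G
            Onew = np.sign(Z) * np.maximum(np.abs(Z) - step * Lam, 0.0)
            Onew = 0.5 * (Onew + Onew.T)
            fnew = smooth(Onew)
            if np.isfinite(fnew):
                D = Onew - Omega
                quad = f + np.sum(G * D) + np.sum(D * D) / (2 * step)
                if fnew <= quad + 1e-12:
                    break
            step *= 0.5
        delta = np.abs(Onew - Omega).max()
        Omega, f = Onew, fnew
        step = min(step * 1.5, 10.0)
        if delta < tol:
            break
    return Omega


def support_constrained_mle(
    S: np.ndarray, pairs: list[tuple[int, int]]
) -> tuple[np.ndarray, float]:
    """Gaussian MLE of the precision matrix with off-diagonal support
    restricted to ``pairs``; returns (Omega, -logdet+tr(Omega S))."""
    S = np.asarray(S, float)
    p = S.shape[0]

    def build(theta):
        O = np.zeros((p, p))
        O[np.diag_indices(p)] = theta[:p]
        for i, (j, k) in enumerate(pairs):
            O[j, k] = O[k, j] = theta[p + i]
        return O

    def fun(theta):
        O = build(theta)
        sign, ld = np.linalg.slogdet(O)
        if sign <= 0:
            return 1e10
        val = -ld + np.sum(O * S)
        return val

    def grad(theta):
        O = build(theta)
        w = np.linalg.eigvalsh(O)
        if w[0] <= 0:
            return np.zeros_like(theta)
        G = S - np.linalg.inv(O)
        g = np.empty_like(theta)
        g[:p] = np.diag(G)
        for i, (j, k) in enumerate(pairs):
            g[p + i] = 2.0 * G[j, k]
        return g

    theta0 = np.concatenate([1.0 / np.diag(S), np.zeros(len(pairs))])
    res = minimize(fun, theta0, jac=grad, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    O = build(res.x)
    return O, fun(res.x)


def best_support_mle(S: np.ndarray, max_pairs: int) -> float:
    """Exhaustive minimum of the Gaussian loss over all symmetric supports
    with at most ``max_pairs`` off-diagonal pairs (diagonal always free)."""
    p = S.shape[0]
    all_pairs = list(itertools.combinations(range(p), 2))
    best = np.inf
    for r in range(max_pairs + 1):
        for pairs in itertools.combinations(all_pairs, r):
            _, val = support_constrained_mle(S, list(pairs))
            best = min(best, val)
    return best
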