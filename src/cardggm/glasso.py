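"""Penalized Gaussian log-likelihood objectives and the graphical lasso solver.

The estimator minimizes

    -logdet(Omega) + tr(Omega S) + sum_jk lam_jk |omega_jk|

over positive definite precision matrices Omega, where the penalty weights
``lam_jk`` are either a single scalar ``lam`` (the classic graphical lasso) or
an element-wise nonnegative symmetric weight matrix (used by the adaptive
lasso and SCAD baselines).  The solver is the block coordinate-descent scheme
that cycles over columns, reducing each column update to a lasso regression
solved by coordinate descent with soft-thresholding.  The penalty covers all
p^2 entries including the diagonal, hence the working covariance is
initialized as ``Sigma_0 = S + lam*I`` and its diagonal stays at
``S_jj + lam_jj`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._cd import glasso_sweep, soft_threshold_scalar
from .covariance import SampleCovariance

__all__ = [
    "PenaltySpec",
    "SolverConfig",
    "PrecisionEstimate",
    "soft_threshold",
    "neg_log_likelihood",
    "penalized_objective",
    "graphical_lasso",
]


@dataclass(frozen=True)
class PenaltySpec:
    """Scalar or element-wise l1 penalty weights.

    ``PenaltySpec(lam=0.1)`` penalizes every entry of Omega by 0.1;
    ``PenaltySpec(weights=Lam)`` supplies a p x p nonnegative symmetric
    weight matrix.
    """

    lam: float | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.lam is None) == (self.weights is None):
            raise ValueError("specify exactly one of lam (scalar) or weights (matrix)")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.weights is not None:
            W = np.asarray(self.weights, dtype=float)
            if W.ndim != 2 or W.shape[0] != W.shape[1]:
                raise ValueError("weight matrix must be square")
            if not np.allclose(W, W.T, atol=1e-10, rtol=0.0):
                raise ValueError("weight matrix must be symmetric")
            if np.any(W < 0):
                raise ValueError("weight matrix must be nonnegative")
            object.__setattr__(self, "weights", W)

    @property
    def mode(self) -> str:
        return "scalar" if self.lam is not None else "matrix"

    def matrix(self, p: int) -> np.ndarray:
        """The full p x p weight matrix this spec expands to."""
        if self.lam is not None:
            return np.full((p, p), float(self.lam))
        if self.weights.shape[0] != p:
            raise ValueError(
                f"weight matrix is {self.weights.shape[0]}x{self.weights.shape[0]}, expected {p}x{p}"
            )
        return self.weights


@dataclass(frozen=True)
class SolverConfig:
    """Convergence controls for the block coordinate-descent solver.

    eps is the threshold on the squared Frobenius norm of the change of
    Omega over one full sweep; inner_tol bounds the max coordinate change
    in the per-column lasso.  pd_floor is recorded for PD diagnostics only:
    positive definiteness is asserted on the converged iterate rather than
    enforced by projection.
    """

    eps: float = 1e-4
    max_outer_iter: int = 200
    inner_tol: float = 1e-6
    inner_max_iter: int = 1000
    pd_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.inner_tol <= 0 or self.pd_floor <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_outer_iter < 1 or self.inner_max_iter < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class PrecisionEstimate:
    """A fitted precision matrix with its running covariance and solver trace."""

    precision: np.ndarray
    covariance: np.ndarray
    iterations: int
    objective_trace: list[float]
    converged: bool

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    def smallest_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.precision)[0])

    def support(self) -> np.ndarray:
        """Boolean off-diagonal support mask (exact zeros)."""
        mask = self.precision != 0.0
        np.fill_diagonal(mask, False)
        return mask


def soft_threshold(x: float, t: float) -> float:
    """sign(x) * max(|x| - t, 0)."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    return soft_threshold_scalar(float(x), float(t))


def _as_matrix(S: SampleCovariance | np.ndarray) -> np.ndarray:
    if isinstance(S, SampleCovariance):
        return S.matrix
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8, rtol=0.0):
        raise ValueError("input matrix must be symmetric")
    return 0.5 * (S + S.T)


def neg_log_likelihood(Omega: np.ndarray, S: SampleCovariance | np.ndarray) -> float:
    """The Gaussian loss -logdet(Omega) + tr(Omega S), up to constants.

    Raises a domain error if Omega is not positive definite.
    """
    Omega = np.asarray(Omega, dtype=float)
    Smat = _as_matrix(S)
    w = np.linalg.eigvalsh(0.5 * (Omega + Omega.T))
    if w[0] <= 0:
        raise ValueError(
            f"precision matrix is not positive definite (smallest eigenvalue {w[0]:.3e})"
        )
    return float(-np.sum(np.log(w)) + np.sum(Omega * Smat))


def penalized_objective(
    Omega: np.ndarray,
    S: SampleCovariance | np.ndarray,
    penalty: PenaltySpec,
) -> float:
    """Negative log-likelihood plus the (possibly weighted) l1 penalty over
    all p^2 entries, diagonal included."""
    Omega = np.asarray(Omega, dtype=float)
    Lam = penalty.matrix(Omega.shape[0])
    return neg_log_likelihood(Omega, S) + float(np.sum(Lam * np.abs(Omega)))


def _objective_or_nan(Omega: np.ndarray, Smat: np.ndarray, Lam: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        return float("nan")
    return float(-logdet + np.sum(Omega * Smat) + np.sum(Lam * np.abs(Omega)))


def _symmetrize_with_support(Omega: np.ndarray) -> np.ndarray:
    """Average Omega with its transpose, but only where both partners are
    nonzero; a zero on either side zeroes both.  Keeps exact zeros exact and
    the support symmetric."""
    both = (Omega != 0.0) & (Omega.T != 0.0)
    out = np.where(both, 0.5 * (Omega + Omega.T), 0.0)
    np.fill_diagonal(out, np.diag(Omega))
    return out


def graphical_lasso(
    S: SampleCovariance | np.ndarray,
    penalty: PenaltySpec | float,
    config: SolverConfig | None = None,
) -> PrecisionEstimate:
    """Block coordinate-descent graphical lasso.

    Parameters
    ----------
    S : SampleCovariance or (p, p) array
        Symmetric input matrix.  May be merely positive semidefinite (or even
        slightly indefinite, as in the DC subproblems): the solver only
        requires the initialization ``S + Lam o I`` to be invertible.
    penalty : PenaltySpec or float
        Scalar penalty or element-wise weight matrix.
    config : SolverConfig
        Convergence controls; defaults per :class:`SolverConfig`.

    Returns
    -------
    PrecisionEstimate
        Precision and covariance iterates; zeros in the precision matrix are
        exact.  ``converged`` is False if ``max_outer_iter`` was exhausted.
    """
    if isinstance(penalty, (int, float)):
        penalty = PenaltySpec(lam=float(penalty))
    if config is None:
        config = SolverConfig()
    Smat = np.ascontiguousarray(_as_matrix(S))
    p = Smat.shape[0]
    Lam = np.ascontiguousarray(penalty.matrix(p))

    Sigma = Smat + np.diag(np.diag(Lam))
    Omega = np.linalg.inv(Sigma)
    trace = [_objective_or_nan(Omega, Smat, Lam)]

    converged = False
    it = 0
    for it in range(1, config.max_outer_iter + 1):
        Omega_prev = Omega.copy()
        glasso_sweep(Smat, Lam, Sigma, Omega, config.inner_tol, config.inner_max_iter)
        trace.append(_objective_or_nan(Omega, Smat, Lam))
        if float(np.sum((Omega - Omega_prev) ** 2)) < config.eps:
            converged = True
            break

    Omega = _symmetrize_with_support(Omega)
    Sigma = 0.5 * (Sigma + Sigma.T)
    return PrecisionEstimate(
        precision=Omega,
        covariance=Sigma,
        iterations=it,
        objective_trace=trace,
        converged=converged,
    )
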