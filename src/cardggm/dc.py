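"""Largest-K norm machinery and the DC algorithm for cardinality-constrained
precision-matrix estimation.

The problem is sparse Gaussian graphical model estimation with a hard budget
``||vec(Omega)||_0 <= K`` on the number of nonzero entries of the p x p
precision matrix (diagonal included).  The cardinality constraint is
rewritten exactly through the largest-K norm |||w|||_K (the sum of the K
largest absolute values): ``||w||_0 <= K  <=>  ||w||_1 - |||w|||_K = 0``,
and the constrained problem is replaced by the penalized difference-of-convex
(DC) objective

    -logdet(Omega) + tr(Omega S) + eta * (||vec(Omega)||_1 - |||vec(Omega)|||_K).

Each DC iteration linearizes the concave part ``-eta |||.|||_K`` at the
incumbent via a subgradient sign matrix V, and the resulting convex
subproblem is exactly a graphical lasso with input matrix ``S - eta V`` and
scalar penalty ``eta`` — the same solver code path as
:func:`cardggm.glasso.graphical_lasso`.  The penalty parameter eta is chosen
adaptively each iteration as the largest power ``alpha^k * lambda_min(S)``
keeping ``S - eta V`` positive definite; every smallest-eigenvalue
computation this takes is counted in the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import SampleCovariance
from .glasso import (
    PenaltySpec,
    PrecisionEstimate,
    SolverConfig,
    graphical_lasso,
    neg_log_likelihood,
)

__all__ = [
    "DCConfig",
    "DCIterationRecord",
    "DCTrace",
    "l0_norm",
    "largest_k_norm",
    "topk_subgradient",
    "subgradient_matrix",
    "find_eta",
    "dc_objective",
    "surrogate_objective",
    "dc_estimate",
    "edge_budget_to_k",
]


def l0_norm(w: np.ndarray) -> int:
    """Number of exactly nonzero entries of w."""
    return int(np.count_nonzero(np.asarray(w)))


def largest_k_norm(w: np.ndarray, K: int) -> float:
    """Sum of the K largest absolute values of w (a norm for each fixed K)."""
    w = np.asarray(w, dtype=float).ravel()
    if not 1 <= K <= w.size:
        raise ValueError(f"K must lie in [1, {w.size}], got {K}")
    a = np.abs(w)
    idx = np.argpartition(a, w.size - K)[w.size - K :]
    return float(a[idx].sum())


def topk_subgradient(w: np.ndarray, K: int) -> np.ndarray:
    """A subgradient of the largest-K norm at w: sign(w_i) on the K positions
    of largest |w_i| (stable lowest-index tie-break), zero elsewhere.

    Satisfies ``s(w) @ w == largest_k_norm(w, K)``.
    """
    w = np.asarray(w, dtype=float).ravel()
    if not 1 <= K <= w.size:
        raise ValueError(f"K must lie in [1, {w.size}], got {K}")
    order = np.argsort(-np.abs(w), kind="stable")
    s = np.zeros(w.size, dtype=np.int8)
    top = order[:K]
    s[top] = np.sign(w[top])
    return s


def subgradient_matrix(Omega: np.ndarray, K: int) -> np.ndarray:
    """The sign matrix V linearizing the largest-K norm at a symmetric Omega.

    The diagonal is always selected first (every diagonal entry of a positive
    definite matrix is nonzero, so ``diag(V) = 1``); the remaining ``K - p``
    slots are filled by the largest off-diagonal absolute values in symmetric
    pairs, largest first, ties broken by lowest (row, column) index.  If
    ``K - p`` is odd the final unpaired slot is left empty so that V — and
    hence the subproblem input ``S - eta V`` — stays symmetric.
    """
    Omega = np.asarray(Omega, dtype=float)
    p = Omega.shape[0]
    if Omega.shape != (p, p) or not np.allclose(Omega, Omega.T, atol=1e-8, rtol=0.0):
        raise ValueError("Omega must be square symmetric")
    if not p <= K <= p * p:
        raise ValueError(f"K must lie in [p, p^2] = [{p}, {p * p}], got {K}")
    if np.any(np.diag(Omega) <= 0):
        raise ValueError("Omega must have strictly positive diagonal entries")

    V = np.zeros((p, p), dtype=float)
    np.fill_diagonal(V, 1.0)
    n_pairs = (K - p) // 2
    if n_pairs > 0:
        iu, ju = np.triu_indices(p, k=1)
        vals = np.abs(Omega[iu, ju])
        order = np.argsort(-vals, kind="stable")  # ties: lowest (row, col) first
        sel = order[:n_pairs]
        sgn = np.sign(Omega[iu[sel], ju[sel]])
        V[iu[sel], ju[sel]] = sgn
        V[ju[sel], iu[sel]] = sgn
    return V


def find_eta(
    S: SampleCovariance | np.ndarray,
    V: np.ndarray,
    alpha: float = 0.5,
    *,
    pd_tolerance: float = 1e-10,
    max_shrinks: int = 60,
) -> tuple[float, int]:
    """Backtracking search for the DC penalty parameter eta.

    Starts from ``lambda_min(S)`` and repeatedly multiplies by
    ``alpha in (0, 1)`` until ``S - eta V`` is positive definite (smallest
    eigenvalue above ``pd_tolerance``).  Returns ``(eta, n_eig)`` where
    ``n_eig`` counts every smallest-eigenvalue computation performed,
    including the initial ``lambda_min(S)``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    Smat = S.matrix if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    lam_min_S = float(np.linalg.eigvalsh(Smat)[0])
    n_eig = 1
    if lam_min_S <= pd_tolerance:
        raise ValueError(
            "smallest eigenvalue of S is not positive "
            f"({lam_min_S:.3e}); apply covariance shrinkage (zeta > 0) to make S "
            "positive definite before calling the DC solver"
        )
    eta = lam_min_S
    for _ in range(max_shrinks):
        eta *= alpha
        n_eig += 1
        if float(np.linalg.eigvalsh(Smat - eta * V)[0]) > pd_tolerance:
            return eta, n_eig
    raise ValueError(
        "eta search failed to make S - eta*V positive definite within "
        f"{max_shrinks} shrinks; S is numerically singular — increase the "
        "covariance shrinkage parameter zeta"
    )


def dc_objective(
    Omega: np.ndarray, S: SampleCovariance | np.ndarray, K: int, eta: float
) -> float:
    """The penalized DC objective: loss plus ``eta*(||.||_1 - |||.|||_K)``.

    The penalty term is always >= 0, and equals 0 exactly when
    ``||vec(Omega)||_0 <= K``.
    """
    w = np.asarray(Omega, dtype=float).ravel()
    gap = float(np.abs(w).sum()) - largest_k_norm(w, K)
    return neg_log_likelihood(Omega, S) + eta * gap


def surrogate_objective(
    Omega: np.ndarray,
    S: SampleCovariance | np.ndarray,
    K: int,
    eta: float,
    Omega_t: np.ndarray,
) -> float:
    """The convex majorizer of the DC objective built by linearizing the
    largest-K norm at the incumbent ``Omega_t``.

    ``g_t(Omega) = -logdet(Omega) + tr(Omega S) + eta||vec(Omega)||_1
    - eta * s(vec(Omega_t))' vec(Omega)``; equals the DC objective at
    ``Omega = Omega_t`` and dominates it elsewhere.
    """
    p = np.asarray(Omega).shape[0]
    V = subgradient_matrix(np.asarray(Omega_t, dtype=float), K)
    w = np.asarray(Omega, dtype=float)
    return (
        neg_log_likelihood(Omega, S)
        + eta * float(np.abs(w).sum())
        - eta * float(np.sum(V * w))
    )


@dataclass(frozen=True)
class DCConfig:
    """Controls for the outer DC loop.

    alpha is the eta-shrinking factor; eps the threshold on the squared
    Frobenius change of Omega between outer iterations.  The initial point
    defaults to ``(S + I)^{-1}``.  The inner graphical lasso uses
    ``glasso_config``.
    """

    alpha: float = 0.5
    eps: float = 1e-4
    max_dc_iter: int = 50
    max_eta_shrinks: int = 60
    pd_tolerance: float = 1e-10
    glasso_config: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class DCIterationRecord:
    eta: float
    n_eig: int
    dc_objective: float
    surrogate_objective: float
    nnz: int


@dataclass
class DCTrace:
    """Per-outer-iteration diagnostics of the DC run."""

    records: list[DCIterationRecord] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    @property
    def n_eig_total(self) -> int:
        return sum(r.n_eig for r in self.records)

    def as_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "n_eig_total": self.n_eig_total,
            "iterations": [
                {
                    "eta": r.eta,
                    "n_eig": r.n_eig,
                    "dc_objective": r.dc_objective,
                    "surrogate_objective": r.surrogate_objective,
                    "nnz": r.nnz,
                }
                for r in self.records
            ],
        }


def edge_budget_to_k(p: int, n_edges: int) -> int:
    """Vec-level cardinality budget allowing ``n_edges`` off-diagonal pairs:
    K = p + 2*n_edges."""
    if n_edges < 0 or n_edges > p * (p - 1) // 2:
        raise ValueError("edge budget out of range")
    return p + 2 * n_edges


def dc_estimate(
    S: SampleCovariance | np.ndarray,
    K: int,
    config: DCConfig | None = None,
    *,
    Omega0: np.ndarray | None = None,
) -> tuple[PrecisionEstimate, DCTrace]:
    """Run the DC algorithm for the cardinality-constrained GGM problem.

    Parameters
    ----------
    S : SampleCovariance or (p, p) array
        Sample covariance; must be positive definite (use shrinkage when
        n < p).
    K : int
        Cardinality budget on vec(Omega), ``p <= K <= p^2``.  The implied
        edge budget is ``(K - p) // 2``.
    config : DCConfig
    Omega0 : array, optional
        Initial precision matrix; defaults to ``(S + I)^{-1}``.

    Returns
    -------
    (PrecisionEstimate, DCTrace)
        The final estimate (zeros exact, from the inner soft-thresholding)
        and the per-iteration record of eta, eigenvalue-computation counts
        and objective values.

    Notes
    -----
    The penalized formulation does not guarantee the hard constraint
    ``||vec(Omega)||_0 <= K`` is met exactly; the trace records the support
    size of every iterate.
    """
    if config is None:
        config = DCConfig()
    Smat = S.matrix if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    p = Smat.shape[0]
    if not p <= K <= p * p:
        raise ValueError(f"K must lie in [p, p^2] = [{p}, {p * p}], got {K}")

    if Omega0 is None:
        Omega = np.linalg.inv(Smat + np.eye(p))
    else:
        Omega = np.asarray(Omega0, dtype=float)
    trace = DCTrace()
    est: PrecisionEstimate | None = None
    converged = False

    for _ in range(config.max_dc_iter):
        V = subgradient_matrix(Omega, K)
        eta, n_eig = find_eta(
            Smat,
            V,
            config.alpha,
            pd_tolerance=config.pd_tolerance,
            max_shrinks=config.max_eta_shrinks,
        )
        est = graphical_lasso(Smat - eta * V, PenaltySpec(lam=eta), config.glasso_config)
        Omega_new = est.precision
        w = Omega_new.ravel()
        gap = float(np.abs(w).sum()) - largest_k_norm(w, K)
        sign, logdet = np.linalg.slogdet(Omega_new)
        nll = float(-logdet + np.sum(Omega_new * Smat)) if sign > 0 else float("nan")
        trace.records.append(
            DCIterationRecord(
                eta=eta,
                n_eig=n_eig,
                dc_objective=nll + eta * gap,
                surrogate_objective=nll
                + eta * float(np.abs(w).sum())
                - eta * float(np.sum(V * Omega_new)),
                nnz=l0_norm(w),
            )
        )
        delta = float(np.sum((Omega_new - Omega) ** 2))
        Omega = Omega_new
        if delta < config.eps:
            converged = True
            break

    result = PrecisionEstimate(
        precision=Omega,
        covariance=est.covariance,
        iterations=trace.n_iterations,
        objective_trace=[r.dc_objective for r in trace.records],
        converged=converged,
    )
    return result, trace
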