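"""Edge-recovery metrics, parameter grids, and K-fold cross-validation.

Edge recovery is scored over the unordered off-diagonal support: TP/FP/FN
counts with exact-zero support reading, composed into precision, recall and
the F1 score.  Cross-validation fits on each training fold's (shrunk) sample
covariance across a grid of the cardinality budget K (DC method) or the
regularization parameter lambda (penalized baselines), scores the Gaussian
log-likelihood ``logdet(Omega) - tr(Omega S_val)`` on the held-out fold, and
selects the grid value maximizing the mean held-out log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import SampleCovariance, sample_covariance, shrink_covariance
from .dc import DCConfig, dc_estimate
from .glasso import PenaltySpec, SolverConfig, graphical_lasso
from .penalties import AdaptiveParams, ScadParams, adaptive_lasso_estimate, scad_estimate
from .synthetic import DEFAULT_ZETA, resolve_zeta

__all__ = [
    "EdgeMetrics",
    "edge_confusion",
    "count_edges",
    "k_grid",
    "lambda_grid",
    "CVResult",
    "cross_validate",
    "fit_method",
]


@dataclass(frozen=True)
class EdgeMetrics:
    """Confusion counts over unordered off-diagonal pairs."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def f1(self) -> float:
        # harmonic mean of precision and recall; 0 by convention when both
        # are undefined or zero (0/0)
        pr, rc = self.precision, self.recall
        return 2.0 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0


def _offdiag_support(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M)
    mask = M != 0.0
    np.fill_diagonal(mask, False)
    return mask


def edge_confusion(Omega_hat: np.ndarray, Omega_true: np.ndarray) -> EdgeMetrics:
    """TP/FP/FN over unordered off-diagonal pairs (exact-zero reading)."""
    Omega_hat = np.asarray(Omega_hat)
    Omega_true = np.asarray(Omega_true)
    if Omega_hat.shape != Omega_true.shape:
        raise ValueError(
            f"shape mismatch: {Omega_hat.shape} vs {Omega_true.shape}"
        )
    iu = np.triu_indices(Omega_hat.shape[0], k=1)
    est = Omega_hat[iu] != 0.0
    tru = Omega_true[iu] != 0.0
    tp = int(np.count_nonzero(est & tru))
    fp = int(np.count_nonzero(est & ~tru))
    fn = int(np.count_nonzero(~est & tru))
    return EdgeMetrics(tp=tp, fp=fp, fn=fn)


def count_edges(Omega: np.ndarray) -> int:
    """Number of unordered off-diagonal pairs with a nonzero entry."""
    return int(np.count_nonzero(_offdiag_support(np.asarray(Omega)))) // 2


def k_grid(p: int, num: int = 100) -> list[int]:
    """``num`` equally spaced values from p+2 to p^2, rounded to integers and
    deduplicated (order preserved)."""
    if p < 2:
        raise ValueError("p must be >= 2")
    vals = np.linspace(p + 2, p * p, num)
    out: list[int] = []
    for v in np.rint(vals).astype(int):
        if not out or v != out[-1]:
            out.append(int(v))
    return out


def lambda_grid(S: SampleCovariance | np.ndarray, num: int = 100) -> list[float]:
    """``num`` equally spaced values in [0, lambda_max] where
    ``lambda_max = max_{j != k} |S_jk|`` — the smallest penalty with an empty
    graphical-lasso support."""
    Smat = S.matrix if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    off = Smat.copy()
    np.fill_diagonal(off, 0.0)
    lam_max = float(np.abs(off).max())
    return list(np.linspace(0.0, lam_max, num))


@dataclass
class CVResult:
    """Cross-validation curve and selection."""

    method: str
    grid: list
    mean_loglik: np.ndarray
    mean_edges: np.ndarray
    selected: float | int
    selected_edges: int
    fold_assignment: np.ndarray
    estimate: object = field(default=None, repr=False)


def fit_method(
    S: SampleCovariance | np.ndarray,
    method: str,
    value: float | int,
    *,
    solver_config: SolverConfig | None = None,
    dc_config: DCConfig | None = None,
    gamma: float = 0.5,
    a: float = 3.7,
):
    """Dispatch a single fit: ``value`` is K for 'dc', lambda otherwise.

    A lambda of exactly 0 is nudged to a tiny positive value so the
    penalized solver remains well defined.
    """
    if method == "dc":
        if dc_config is None:
            dc_config = DCConfig(glasso_config=solver_config or SolverConfig())
        est, _ = dc_estimate(S, int(value), dc_config)
        return est
    lam = max(float(value), 1e-8)
    if method == "glasso":
        return graphical_lasso(S, PenaltySpec(lam=lam), solver_config)
    if method == "adaptive":
        return adaptive_lasso_estimate(S, AdaptiveParams(lam=lam, gamma=gamma), solver_config)
    if method == "scad":
        return scad_estimate(S, ScadParams(lam=lam, a=a), solver_config)
    raise ValueError(f"unknown method {method!r}")


def _holdout_loglik(Omega: np.ndarray, S_val: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.sum(Omega * S_val))


def cross_validate(
    data: np.ndarray,
    method: str,
    grid: list,
    *,
    folds: int = 5,
    seed: int | np.random.Generator = 0,
    zeta: float | str = DEFAULT_ZETA,
    solver_config: SolverConfig | None = None,
    dc_config: DCConfig | None = None,
    refit: bool = True,
) -> CVResult:
    """K-fold cross-validation over a grid of K (DC) or lambda (baselines).

    Each fold's training covariance is centered by the training mean,
    shrunk by ``zeta``, and fitted at every grid value; the held-out fold is
    scored by ``logdet(Omega) - tr(Omega S_val)`` with its own mean and
    divisor n_val (no shrinkage on the validation side).  The grid value
    maximizing the mean held-out log-likelihood is selected; ties go to the
    sparser model (smaller K, larger lambda).
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if n < folds:
        raise ValueError("need at least as many observations as folds")
    grid = list(dict.fromkeys(grid))  # deduplicate, order preserved
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n) % folds

    scores = np.zeros((folds, len(grid)))
    edges = np.zeros((folds, len(grid)))
    for f in range(folds):
        train, val = X[assignment != f], X[assignment == f]
        S_train = shrink_covariance(sample_covariance(train), resolve_zeta(zeta, train))
        S_val = sample_covariance(val).matrix
        for gi, value in enumerate(grid):
            est = fit_method(
                S_train, method, value, solver_config=solver_config, dc_config=dc_config
            )
            scores[f, gi] = _holdout_loglik(est.precision, S_val)
            edges[f, gi] = count_edges(est.precision)

    mean_scores = scores.mean(axis=0)
    best = mean_scores.max()
    maximizers = [gi for gi, s in enumerate(mean_scores) if s == best]
    if method == "dc":
        sel_idx = min(maximizers, key=lambda gi: grid[gi])  # smallest K
    else:
        sel_idx = max(maximizers, key=lambda gi: grid[gi])  # largest lambda
    selected = grid[sel_idx]

    estimate = None
    selected_edges = int(round(edges[:, sel_idx].mean()))
    if refit:
        S_full = shrink_covariance(sample_covariance(X), resolve_zeta(zeta, X))
        estimate = fit_method(
            S_full, method, selected, solver_config=solver_config, dc_config=dc_config
        )
        selected_edges = count_edges(estimate.precision)

    return CVResult(
        method=method,
        grid=grid,
        mean_loglik=mean_scores,
        mean_edges=edges.mean(axis=0),
        selected=selected,
        selected_edges=selected_edges,
        fold_assignment=assignment,
        estimate=estimate,
    )
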