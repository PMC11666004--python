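"""Sample covariance containers, shrinkage and delimited-text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SampleCovariance",
    "sample_covariance",
    "shrink_covariance",
    "estimate_shrinkage_intensity",
    "read_matrix",
    "write_matrix",
    "write_edge_list",
]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class SampleCovariance:
    """A symmetric second-moment summary of an n x p data matrix.

    Parameters
    ----------
    matrix : (p, p) ndarray
        The sample covariance ``S = (1/n) sum_i (x_i - m)(x_i - m)^T``
        (divisor ``n``, data centered by the sample mean ``m``).
    n : int, optional
        Number of observations used to form ``S``; kept for
        cross-validation bookkeeping, not used by the solvers.
    mean : (p,) ndarray, optional
        The sample mean the data were centered by.
    """

    matrix: np.ndarray
    n: int | None = None
    mean: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.matrix, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError(f"covariance must be square, got shape {S.shape}")
        if S.shape[0] < 2:
            raise ValueError("need at least p = 2 variables")
        if not np.allclose(S, S.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("covariance matrix is not symmetric within 1e-10")
        if np.any(np.diag(S) < 0):
            raise ValueError("covariance diagonal has negative entries")
        object.__setattr__(self, "matrix", 0.5 * (S + S.T))

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def smallest_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


def sample_covariance(data: np.ndarray | pd.DataFrame, *, ddof: int = 0) -> SampleCovariance:
    """Center ``data`` by its sample mean and form S with divisor ``n - ddof``.

    The default ``ddof=0`` is the maximum-likelihood convention
    ``S = (1/n) sum (x_i - m)(x_i - m)^T``.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D (observations x variables) array")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two observations")
    m = X.mean(axis=0)
    Xc = X - m
    S = (Xc.T @ Xc) / (n - ddof)
    return SampleCovariance(matrix=0.5 * (S + S.T), n=n, mean=m)


def shrink_covariance(S: SampleCovariance | np.ndarray, zeta: float) -> SampleCovariance:
    """Shrink the off-diagonal of S toward zero: ``S <- zeta*D_S + (1-zeta)*S``.

    ``D_S`` is the diagonal part of S, so the diagonal is unchanged and every
    off-diagonal entry is scaled by ``1 - zeta``.  With ``zeta > 0`` this
    improves conditioning, which matters when n < p leaves S singular.
    """
    if not 0.0 <= zeta <= 1.0:
        raise ValueError(f"shrinkage parameter zeta must lie in [0, 1], got {zeta}")
    if isinstance(S, SampleCovariance):
        M, n, mean = S.matrix, S.n, S.mean
    else:
        M, n, mean = np.asarray(S, dtype=float), None, None
    D = np.diag(np.diag(M))
    return SampleCovariance(matrix=zeta * D + (1.0 - zeta) * M, n=n, mean=mean)


def estimate_shrinkage_intensity(data: np.ndarray) -> float:
    """Analytic optimal intensity for shrinking the off-diagonal of S to zero.

    The diagonal-target shrinkage estimator replaces S by
    ``zeta*D_S + (1-zeta)*S`` with intensity

        zeta* = sum_{j != k} Var^(s_jk) / sum_{j != k} s_jk^2,

    clipped to [0, 1], where ``Var^(s_jk)`` is the usual unbiased estimate of
    the sampling variance of the covariance entry.  This minimizes the
    expected squared error of the shrunk estimate and adapts to the n/p
    regime: heavy shrinkage when n << p, little when n >> p.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least three observations to estimate the intensity")
    Xc = X - X.mean(axis=0)
    wbar = (Xc.T @ Xc) / n  # mean of w_ijk = xc_ij * xc_ik
    sq = Xc**2
    sum_w2 = sq.T @ sq  # sum_i w_ijk^2
    var_s = n / (n - 1.0) ** 3 * (sum_w2 - n * wbar**2)
    s_unb = n / (n - 1.0) * wbar
    mask = ~np.eye(p, dtype=bool)
    denom = float(np.sum(s_unb[mask] ** 2))
    if denom <= 0.0:
        return 1.0
    return float(np.clip(np.sum(var_s[mask]) / denom, 0.0, 1.0))


def read_matrix(path: str | Path, *, header: bool = False) -> np.ndarray:
    """Read a numeric matrix from delimited text (CSV/TSV sniffed by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, header=0 if header else None)
    return df.to_numpy(dtype=float)


def write_matrix(M: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pd.DataFrame(np.asarray(M)).to_csv(path, sep=sep, header=False, index=False)


def write_edge_list(Omega: np.ndarray, path: str | Path) -> None:
    """Write the off-diagonal support as TSV (node_i, node_j, weight), 1-based,
    upper triangle only."""
    Omega = np.asarray(Omega)
    rows = []
    p = Omega.shape[0]
    for j in range(p):
        for k in range(j + 1, p):
            if Omega[j, k] != 0.0:
                rows.append((j + 1, k + 1, Omega[j, k]))
    df = pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])
    df.to_csv(path, sep="\t", index=False)
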