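"""Ground-truth precision matrices and Gaussian sampling for benchmarks.

Two graph families are generated:

* **random** — a symmetrized standard-normal matrix whose off-diagonal is
  sparsified down to a chosen number of edges, then shifted by ``eta_rnd * I``
  so its smallest eigenvalue is exactly 1;
* **chain** — the banded matrix with 1 on the diagonal, 0.5 on the first and
  0.25 on the second off-diagonals, with band entries zeroed in symmetric
  pairs until the requested edge count remains.

Data are i.i.d. draws from N(0, Sigma*) with Sigma* = (Omega*)^{-1}; the
sample covariance may then be shrunk toward its diagonal
(``S <- zeta*D_S + (1-zeta)*S``) to guarantee positive definiteness when
n < p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariance import (
    SampleCovariance,
    estimate_shrinkage_intensity,
    sample_covariance,
    shrink_covariance,
)

__all__ = [
    "GroundTruthModel",
    "make_random_graph_precision",
    "make_chain_graph_precision",
    "sample_dataset",
    "make_benchmark",
    "resolve_zeta",
    "DEFAULT_ZETA",
]

#: Default covariance-shrinkage intensity: "auto" estimates the analytic
#: optimal diagonal-target intensity from the data (see
#: :func:`cardggm.covariance.estimate_shrinkage_intensity`).
DEFAULT_ZETA = "auto"


def resolve_zeta(zeta, X: np.ndarray) -> float:
    """Resolve a shrinkage setting to a number: 'auto' estimates the analytic
    optimal intensity from the data matrix X, a float passes through."""
    if isinstance(zeta, str):
        if zeta != "auto":
            raise ValueError(f"unknown shrinkage setting {zeta!r}")
        return estimate_shrinkage_intensity(X)
    return float(zeta)

_CHAIN_RETRIES = 100


@dataclass(frozen=True)
class GroundTruthModel:
    """A true precision matrix with its covariance and edge set."""

    precision: np.ndarray
    covariance: np.ndarray
    edge_set: frozenset[tuple[int, int]]
    graph_kind: str

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def n_true_edges(self) -> int:
        return len(self.edge_set)


def _choose_pairs(rng: np.random.Generator, p: int, n_keep: int, candidates=None):
    if candidates is None:
        iu, ju = np.triu_indices(p, k=1)
        candidates = list(zip(iu.tolist(), ju.tolist()))
    idx = rng.choice(len(candidates), size=n_keep, replace=False)
    return [candidates[i] for i in sorted(idx.tolist())]


def make_random_graph_precision(
    p: int, n_true_edges: int, seed: int | np.random.Generator
) -> GroundTruthModel:
    """Random-graph truth: symmetrized N(0,1) matrix, sparsified to exactly
    ``n_true_edges`` off-diagonal pairs, shifted so lambda_min = 1."""
    if not 0 <= n_true_edges <= p * (p - 1) // 2:
        raise ValueError("n_true_edges out of range for p variables")
    rng = np.random.default_rng(seed)
    A1 = rng.standard_normal((p, p))
    A2 = 0.5 * (A1 + A1.T)
    keep = _choose_pairs(rng, p, n_true_edges)
    mask = np.zeros((p, p), dtype=bool)
    for j, k in keep:
        mask[j, k] = mask[k, j] = True
    off = np.where(mask, A2, 0.0)
    np.fill_diagonal(off, np.diag(A2))  # diagonal kept as drawn
    lam_min = np.linalg.eigvalsh(off)[0]
    Omega = off + (1.0 - lam_min) * np.eye(p)
    edges = frozenset((j, k) for j, k in keep if Omega[j, k] != 0.0)
    return GroundTruthModel(
        precision=Omega,
        covariance=np.linalg.inv(Omega),
        edge_set=edges,
        graph_kind="random",
    )


def make_chain_graph_precision(
    p: int, n_true_edges: int, seed: int | np.random.Generator
) -> GroundTruthModel:
    """Chain-graph truth: banded (1, 0.5, 0.25) matrix with band pairs zeroed
    down to ``n_true_edges``; redraws the zero pattern (bounded retries) if
    the result loses positive definiteness."""
    band = [(j, j + 1) for j in range(p - 1)] + [(j, j + 2) for j in range(p - 2)]
    if not 0 <= n_true_edges <= len(band):
        raise ValueError(
            f"n_true_edges must lie in [0, {len(band)}] for the chain band, got {n_true_edges}"
        )
    rng = np.random.default_rng(seed)
    base = np.eye(p)
    for j, k in band:
        base[j, k] = base[k, j] = 0.5 if k - j == 1 else 0.25
    for _ in range(_CHAIN_RETRIES):
        keep = _choose_pairs(rng, p, n_true_edges, candidates=band)
        Omega = np.eye(p)
        for j, k in keep:
            Omega[j, k] = Omega[k, j] = base[j, k]
        if np.linalg.eigvalsh(Omega)[0] > 0:
            edges = frozenset(keep)
            return GroundTruthModel(
                precision=Omega,
                covariance=np.linalg.inv(Omega),
                edge_set=edges,
                graph_kind="chain",
            )
    raise RuntimeError(
        "could not find a positive definite chain pattern after "
        f"{_CHAIN_RETRIES} redraws"
    )


def sample_dataset(
    model: GroundTruthModel, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n i.i.d. observations from N(0, Sigma*)."""
    if n < 2:
        raise ValueError("need n >= 2 observations")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(model.covariance)
    Z = rng.standard_normal((n, model.p))
    return Z @ L.T


def make_benchmark(
    graph: str,
    p: int,
    n: int,
    n_true_edges: int = 30,
    zeta: float | str = DEFAULT_ZETA,
    seed: int | np.random.Generator = 0,
) -> tuple[GroundTruthModel, np.ndarray, SampleCovariance]:
    """One full benchmark instance: truth, data, and shrunk sample covariance.

    ``zeta='auto'`` (the default) estimates the shrinkage intensity from the
    sampled data; a float fixes it.
    """
    rng = np.random.default_rng(seed)
    if graph == "random":
        model = make_random_graph_precision(p, n_true_edges, rng)
    elif graph == "chain":
        model = make_chain_graph_precision(p, n_true_edges, rng)
    else:
        raise ValueError(f"unknown graph kind {graph!r} (expected 'random' or 'chain')")
    X = sample_dataset(model, n, rng)
    S = shrink_covariance(sample_covariance(X), resolve_zeta(zeta, X))
    return model, X, S
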