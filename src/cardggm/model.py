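"""Model/Results interface over the estimators.

:class:`GaussianGraphicalModel` is built from a data matrix (or directly
from a sample covariance); its :meth:`~GaussianGraphicalModel.fit` dispatches
to the cardinality-constrained DC solver or one of the penalized baselines
and returns a :class:`GGMResults` carrying the precision estimate, solver
diagnostics, the recovered edge list and a ``summary()`` table.
Cross-validated selection of the sparsity parameter is available through
:meth:`~GaussianGraphicalModel.fit_cv`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariance import SampleCovariance, sample_covariance, shrink_covariance
from .dc import DCConfig, DCTrace, dc_estimate, edge_budget_to_k
from .glasso import PenaltySpec, PrecisionEstimate, SolverConfig, graphical_lasso
from .penalties import AdaptiveParams, ScadParams, adaptive_lasso_estimate, scad_estimate
from .selection import CVResult, count_edges, cross_validate, k_grid, lambda_grid
from .synthetic import resolve_zeta

__all__ = ["GaussianGraphicalModel", "GGMResults"]


class GaussianGraphicalModel:
    """Sparse Gaussian graphical model estimation for an n x p data matrix.

    Parameters
    ----------
    data : (n, p) array-like, optional
        Observations by variables; centered internally by the sample mean.
    cov : SampleCovariance or (p, p) array, optional
        Alternatively, a precomputed sample covariance.
    zeta : float
        Shrinkage intensity applied to the sample covariance
        (``S <- zeta*D_S + (1-zeta)*S``); required to be > 0 for the DC
        method when n < p leaves S singular.
    names : sequence of str, optional
        Variable names used in summaries and edge lists.

    Examples
    --------
    >>> model = GaussianGraphicalModel(X, zeta=0.2)
    >>> res = model.fit(method="dc", n_edges=30)
    >>> res.edges()  # doctest: +SKIP
    """

    def __init__(self, data=None, *, cov=None, zeta: float | str = 0.0, names=None):
        if (data is None) == (cov is None):
            raise ValueError("supply exactly one of data or cov")
        if data is not None:
            data = np.asarray(data, dtype=float)
            if isinstance(data, np.ndarray) and data.ndim != 2:
                raise ValueError("data must be 2-D (observations x variables)")
            self.data = data
            S = sample_covariance(data)
        else:
            self.data = None
            if zeta == "auto":
                raise ValueError("zeta='auto' needs the raw data matrix")
            S = cov if isinstance(cov, SampleCovariance) else SampleCovariance(np.asarray(cov, float))
        self.zeta = resolve_zeta(zeta, self.data)
        self.cov = shrink_covariance(S, self.zeta) if self.zeta > 0 else S
        self.names = list(names) if names is not None else [f"x{i+1}" for i in range(S.p)]
        if len(self.names) != S.p:
            raise ValueError("names length does not match number of variables")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, zeta: float = 0.0) -> "GaussianGraphicalModel":
        return cls(df.to_numpy(dtype=float), zeta=zeta, names=list(df.columns))

    @classmethod
    def from_covariance(
        cls, S, n: int | None = None, *, zeta: float = 0.0, names=None
    ) -> "GaussianGraphicalModel":
        if not isinstance(S, SampleCovariance):
            S = SampleCovariance(np.asarray(S, dtype=float), n=n)
        return cls(cov=S, zeta=zeta, names=names)

    @property
    def p(self) -> int:
        return self.cov.p

    def fit(
        self,
        method: str = "dc",
        *,
        K: int | None = None,
        n_edges: int | None = None,
        lam: float | None = None,
        gamma: float = 0.5,
        a: float = 3.7,
        alpha: float = 0.5,
        eps: float = 1e-4,
        solver_config: SolverConfig | None = None,
        dc_config: DCConfig | None = None,
    ) -> "GGMResults":
        """Fit the model.

        method='dc' takes a cardinality budget ``K`` (nonzeros of vec(Omega),
        diagonal included) or an edge budget ``n_edges`` (K = p + 2*n_edges);
        the other methods ('glasso', 'adaptive', 'scad') take a penalty
        ``lam``.
        """
        trace: DCTrace | None = None
        if method == "dc":
            if (K is None) == (n_edges is None):
                raise ValueError("dc fit needs exactly one of K or n_edges")
            if K is None:
                K = edge_budget_to_k(self.p, n_edges)
            if dc_config is None:
                dc_config = DCConfig(
                    alpha=alpha, eps=eps,
                    glasso_config=solver_config or SolverConfig(eps=eps),
                )
            est, trace = dc_estimate(self.cov, K, dc_config)
            param = {"K": K}
        else:
            if lam is None:
                raise ValueError(f"method {method!r} needs lam")
            cfg = solver_config or SolverConfig(eps=eps)
            if method == "glasso":
                est = graphical_lasso(self.cov, PenaltySpec(lam=lam), cfg)
            elif method == "adaptive":
                est = adaptive_lasso_estimate(self.cov, AdaptiveParams(lam=lam, gamma=gamma), cfg)
            elif method == "scad":
                est = scad_estimate(self.cov, ScadParams(lam=lam, a=a), cfg)
            else:
                raise ValueError(f"unknown method {method!r}")
            param = {"lam": lam}
        return GGMResults(self, method, param, est, trace)

    def fit_cv(
        self,
        method: str = "dc",
        *,
        grid=None,
        folds: int = 5,
        seed: int = 0,
        grid_size: int = 100,
        solver_config: SolverConfig | None = None,
        dc_config: DCConfig | None = None,
    ) -> "GGMResults":
        """Select K (DC) or lambda (baselines) by K-fold cross-validation on
        the raw data, then refit on the full sample."""
        if self.data is None:
            raise ValueError("cross-validation needs the raw data matrix")
        if grid is None:
            grid = (
                k_grid(self.p, grid_size)
                if method == "dc"
                else lambda_grid(self.cov, grid_size)
            )
        cv = cross_validate(
            self.data, method, grid,
            folds=folds, seed=seed, zeta=self.zeta,
            solver_config=solver_config, dc_config=dc_config,
        )
        param = {("K" if method == "dc" else "lam"): cv.selected}
        res = GGMResults(self, method, param, cv.estimate, None)
        res.cv = cv
        return res


class GGMResults:
    """Results of a sparse GGM fit.

    Attributes
    ----------
    precision, covariance : (p, p) ndarray
        The estimated precision matrix (zeros exact) and the solver's
        companion covariance.
    trace : DCTrace or None
        Per-iteration eta, eigenvalue-computation counts and objectives
        (DC method only).
    cv : CVResult or None
        The cross-validation curve when fitted via ``fit_cv``.
    """

    def __init__(self, model, method, param, estimate: PrecisionEstimate, trace):
        self.model = model
        self.method = method
        self.param = param
        self._estimate = estimate
        self.trace = trace
        self.cv: CVResult | None = None

    @property
    def precision(self) -> np.ndarray:
        return self._estimate.precision

    @property
    def covariance(self) -> np.ndarray:
        return self._estimate.covariance

    @property
    def converged(self) -> bool:
        return self._estimate.converged

    @property
    def n_edges(self) -> int:
        return count_edges(self.precision)

    def edges(self) -> pd.DataFrame:
        """Recovered edges as a tidy frame (upper triangle, 1-based indices)."""
        names = self.model.names
        rows = []
        p = self.precision.shape[0]
        for j in range(p):
            for k in range(j + 1, p):
                w = self.precision[j, k]
                if w != 0.0:
                    rows.append((j + 1, k + 1, names[j], names[k], w))
        return pd.DataFrame(
            rows, columns=["node_i", "node_j", "name_i", "name_j", "weight"]
        )

    def partial_correlations(self) -> np.ndarray:
        """Partial correlation matrix: -omega_jk / sqrt(omega_jj * omega_kk)."""
        d = np.sqrt(np.diag(self.precision))
        P = -self.precision / np.outer(d, d)
        np.fill_diagonal(P, 1.0)
        return P

    def to_networkx(self):
        """The conditional-independence graph as a networkx Graph (weights =
        precision entries)."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.model.names)
        for _, r in self.edges().iterrows():
            G.add_edge(r["name_i"], r["name_j"], weight=r["weight"])
        return G

    def summary(self) -> str:
        est = self._estimate
        lines = [
            "Sparse Gaussian Graphical Model Results",
            "=" * 46,
            f"Method:               {self.method}",
            f"Variables (p):        {self.model.p}",
            f"Observations (n):     {self.model.cov.n if self.model.cov.n else 'n/a'}",
            f"Shrinkage zeta:       {self.model.zeta:.4g}",
        ]
        for k, v in self.param.items():
            lines.append(f"{k + ':':<22}{v:g}")
        lines += [
            f"Selected edges:       {self.n_edges}",
            f"Converged:            {est.converged}",
            f"Smallest eigenvalue:  {est.smallest_eigenvalue():.4g}",
        ]
        if self.trace is not None:
            lines += [
                f"DC iterations:        {self.trace.n_iterations}",
                f"Eigenvalue calcs:     {self.trace.n_eig_total}",
                f"Final DC objective:   {self.trace.records[-1].dc_objective:.6g}",
            ]
        if self.cv is not None:
            lines.append(f"CV grid size:         {len(self.cv.grid)}")
        return "\n".join(lines)

    def plot_graph(self, ax=None, **kwargs):
        """Draw the recovered conditional-independence graph (spring layout)."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots()
        G = self.to_networkx()
        nx.draw_networkx(G, ax=ax, node_size=300, font_size=8, **kwargs)
        ax.set_axis_off()
        return ax
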