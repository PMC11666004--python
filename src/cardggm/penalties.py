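"""Baseline penalized estimators: adaptive lasso and SCAD.

Both are handled through the element-wise weighted graphical lasso: the
adaptive lasso is a single weighted fit with weights ``1/|omega~_jk|^gamma``
from a pilot estimate, and SCAD is solved by iterated local linear
approximation (LLA) — repeated weighted fits with weights equal to the SCAD
derivative at the current estimate's magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import SampleCovariance
from .glasso import PenaltySpec, PrecisionEstimate, SolverConfig, graphical_lasso

__all__ = [
    "ScadParams",
    "AdaptiveParams",
    "scad_penalty",
    "scad_derivative",
    "adaptive_weights",
    "adaptive_lasso_estimate",
    "scad_estimate",
]

#: Cap for adaptive weights at zero pilot entries (effectively forbids the edge).
WEIGHT_CAP = 1e12

#: Ridge added to S when inverting a singular pilot covariance (n < p).
PILOT_RIDGE = 1e-3


@dataclass(frozen=True)
class ScadParams:
    lam: float
    a: float = 3.7

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.a <= 2:
            raise ValueError(f"SCAD requires a > 2, got a = {self.a}")


@dataclass(frozen=True)
class AdaptiveParams:
    lam: float
    gamma: float = 0.5
    pilot: np.ndarray | None = None  # defaults to S^{-1} (ridge-stabilized)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def scad_penalty(x: float | np.ndarray, lam: float, a: float = 3.7) -> float | np.ndarray:
    """The smoothly clipped absolute deviation penalty.

    Piecewise: ``lam|x|`` for ``|x| <= lam``; a quadratic blend
    ``(a*lam*|x| - (x^2 + lam^2)/2)/(a - 1)`` for ``lam < |x| <= a*lam``;
    constant ``(a + 1)*lam^2/2`` beyond — continuous at both breakpoints,
    unbiased for large signals.
    """
    if a <= 2:
        raise ValueError(f"SCAD requires a > 2, got a = {a}")
    if lam <= 0:
        raise ValueError("lam must be positive")
    ax = np.abs(np.asarray(x, dtype=float))
    out = np.where(
        ax <= lam,
        lam * ax,
        np.where(
            ax <= a * lam,
            (a * lam * ax - (ax**2 + lam**2) / 2.0) / (a - 1.0),
            (a + 1.0) * lam**2 / 2.0,
        ),
    )
    return float(out) if np.isscalar(x) else out


def scad_derivative(x: float | np.ndarray, lam: float, a: float = 3.7) -> float | np.ndarray:
    """d/d|x| of the SCAD penalty: lam on [0, lam], linearly decaying to 0 at
    a*lam, then 0 (the unbiasedness region)."""
    if a <= 2:
        raise ValueError(f"SCAD requires a > 2, got a = {a}")
    ax = np.abs(np.asarray(x, dtype=float))
    out = np.where(
        ax <= lam,
        lam,
        np.maximum(a * lam - ax, 0.0) / (a - 1.0),
    )
    return float(out) if np.isscalar(x) else out


def adaptive_weights(pilot: np.ndarray, gamma: float) -> np.ndarray:
    """Element-wise weights ``1/|omega~_jk|^gamma``; zero pilot entries get the
    capped weight ``1e12``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    A = np.abs(np.asarray(pilot, dtype=float))
    with np.errstate(divide="ignore"):
        W = 1.0 / A**gamma
    return np.minimum(W, WEIGHT_CAP)


def _default_pilot(Smat: np.ndarray) -> np.ndarray:
    """Pilot precision estimate S^{-1}; ridge-stabilized when S is singular."""
    w = np.linalg.eigvalsh(Smat)
    if w[0] <= 1e-10:
        Smat = Smat + PILOT_RIDGE * np.eye(Smat.shape[0])
    return np.linalg.inv(Smat)


def adaptive_lasso_estimate(
    S: SampleCovariance | np.ndarray,
    params: AdaptiveParams,
    config: SolverConfig | None = None,
) -> PrecisionEstimate:
    """Adaptive lasso: one weighted graphical lasso fit with penalty matrix
    ``lam * adaptive_weights(pilot, gamma)``."""
    Smat = S.matrix if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    pilot = params.pilot if params.pilot is not None else _default_pilot(Smat)
    Lam = params.lam * adaptive_weights(pilot, params.gamma)
    Lam = 0.5 * (Lam + Lam.T)
    return graphical_lasso(Smat, PenaltySpec(weights=Lam), config)


def scad_estimate(
    S: SampleCovariance | np.ndarray,
    params: ScadParams,
    config: SolverConfig | None = None,
    *,
    max_rounds: int = 5,
) -> PrecisionEstimate:
    """SCAD-penalized estimation by iterated local linear approximation.

    Round r solves a weighted graphical lasso with weights equal to the SCAD
    derivative at the magnitudes of round r-1's estimate (round 1 starts from
    the flat weight lam, i.e. plain graphical lasso).  Stops when the
    off-diagonal support stabilizes or after ``max_rounds`` rounds.
    """
    Smat = S.matrix if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    est = graphical_lasso(Smat, PenaltySpec(lam=params.lam), config)
    support = est.precision != 0.0
    for _ in range(max_rounds - 1):
        Lam = scad_derivative(est.precision, params.lam, params.a)
        # keep the diagonal penalized at its SCAD derivative value, as for
        # every other entry; symmetry is inherited from est.precision
        est = graphical_lasso(Smat, PenaltySpec(weights=np.asarray(Lam)), config)
        new_support = est.precision != 0.0
        if np.array_equal(new_support, support):
            break
        support = new_support
    return est
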