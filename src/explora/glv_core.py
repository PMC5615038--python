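"""Fixed points, Jacobians and spectral abscissas for the simple
generalized Lotka-Volterra case  dx_i/dt = x_i (alpha_i + sum_j w_ij x_j).

The Jacobian at a stationary point x* is J_ij = x*_i w_ij, so local
stability is decided by the sign of the spectral abscissa (maximum real
part of the eigenvalues) of diag(x*) w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._exceptions import InvalidParameterError, SingularMatrixError
from .topology import AdjacencyMask

__all__ = [
    "InteractionMatrix",
    "FixedPoint",
    "Trajectory",
    "fixed_point",
    "spectral_abscissa",
    "integrate_glv",
]

#: Condition-number cap above which a weight matrix is treated as singular.
CONDITION_CAP = 1e12


@dataclass(frozen=True)
class InteractionMatrix:
    """S x S weight matrix with diagonal fixed at -1 and zeros wherever
    the adjacency mask is inactive."""

    weights: np.ndarray
    mask: AdjacencyMask

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError("weights must be square")
        if w.shape[0] != self.mask.n_nodes:
            raise InvalidParameterError("weights and mask size mismatch")
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("weights must be finite")
        if not np.allclose(np.diagonal(w), -1.0):
            raise InvalidParameterError("diagonal entries must equal -1")
        if np.any(w[~self.mask.active] != 0.0):
            raise InvalidParameterError("nonzero weight outside the mask")

    @property
    def n_nodes(self) -> int:
        return int(self.weights.shape[0])


@dataclass(frozen=True)
class FixedPoint:
    """Stationary state x* = -w^{-1} alpha with its feasibility flag and
    the spectral abscissa of the Jacobian there."""

    x_star: np.ndarray
    feasible: bool
    spectral_abscissa: float


@dataclass(frozen=True)
class Trajectory:
    """End state of a numerical integration, with a divergence flag."""

    t_end: float
    x_end: np.ndarray
    diverged: bool


def _weights_of(w) -> np.ndarray:
    return w.weights if isinstance(w, InteractionMatrix) else np.asarray(w, float)


def spectral_abscissa(w, x_star: np.ndarray) -> float:
    """Maximum real part of the eigenvalues of J_ij = x*_i w_ij."""
    W = _weights_of(w)
    x = np.asarray(x_star, dtype=float)
    if x.size != W.shape[0]:
        raise InvalidParameterError("x_star length does not match matrix size")
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(x))):
        raise InvalidParameterError("non-finite input")
    J = x[:, None] * W
    return float(np.max(np.linalg.eigvals(J).real))


def fixed_point(w, alpha) -> FixedPoint:
    """Solve w x* = -alpha and report feasibility and local stability.

    Raises
    ------
    SingularMatrixError
        If the condition number of ``w`` exceeds :data:`CONDITION_CAP`.
    """
    W = _weights_of(w)
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (W.shape[0],))
    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > CONDITION_CAP:
        raise SingularMatrixError(
            f"weight matrix is singular or ill-conditioned (cond~{cond:.3g})"
        )
    x = np.linalg.solve(W, -a)
    resid = np.max(np.abs(W @ x + a))
    scale = max(np.max(np.abs(a)), 1.0)
    if resid > 1e-10 * scale:
        raise SingularMatrixError(
            f"linear solve residual {resid:.3g} exceeds tolerance"
        )
    return FixedPoint(
        x_star=x,
        feasible=bool(np.min(x) > 0),
        spectral_abscissa=spectral_abscissa(W, x),
    )


def integrate_glv(
    w,
    alpha,
    x0: np.ndarray,
    t_max: float = 100.0,
    dt: float | None = None,
    blowup_cap: float = 1e6,
) -> Trajectory:
    """Integrate dx_i/dt = x_i (alpha_i + (w x)_i) from ``x0``.

    A validation oracle, not a production integrator: adaptive RK45 with
    tight tolerances, stopping early if any component exceeds
    ``blowup_cap`` (reported as divergence, not an exception).
    """
    W = _weights_of(w)
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (W.shape[0],)).copy()
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise InvalidParameterError("initial state must be strictly positive")

    def rhs(t, x):
        return x * (a + W @ x)

    def blowup(t, x):
        return float(blowup_cap - np.max(np.abs(x)))

    blowup.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        x0,
        method="RK45",
        rtol=1e-8,
        atol=1e-9,
        max_step=dt if dt else np.inf,
        events=blowup,
    )
    diverged = bool(sol.t_events[0].size) or not sol.success
    return Trajectory(t_end=float(sol.t[-1]), x_end=sol.y[:, -1], diverged=diverged)
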