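"""Stochastic hill climbing of the fixed extra-link weights.

Link *locations* never move; every step perturbs all weights at once
with zero-mean Gaussian noise of std ``step_std`` and accepts the
proposal only if the optimized quantity strictly increases.  The
robustness objective is re-estimated from fresh perturbation draws at
every evaluation, so its measured landscape is noisy -- which is what
makes joint optimization stall on dense networks.  Final values should
be recomputed at full sampling with :func:`evaluate_network`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import InvalidParameterError, NotApplicableError
from .explorability import scan_marginal_homogeneous
from .robustness import edge_matrix, robustness_R
from .topology import ExtraLinks, TreeLikeTopology

__all__ = [
    "OptimizationConfig",
    "OptimizationTrace",
    "TraceStep",
    "hill_climb",
    "multi_objective_climb",
    "evaluate_network",
]

OBJECTIVES = ("explorability", "robustness", "both", "alternating")


@dataclass(frozen=True)
class OptimizationConfig:
    objective: str = "explorability"
    steps: int = 200
    step_std: float = 0.01
    seed: int | None = None
    n_xi: int = 200
    percentile: int = 5
    alternating_period: int = 20
    alpha_value: float = 1.0

    def __post_init__(self):
        if self.objective not in OBJECTIVES:
            raise InvalidParameterError(
                f"objective must be one of {OBJECTIVES}, got {self.objective!r}"
            )
        if self.steps < 1:
            raise InvalidParameterError("steps must be >= 1")
        # supported range; 0 is allowed as the degenerate no-move case
        if self.step_std != 0 and not (1e-3 <= self.step_std <= 1e-1):
            raise InvalidParameterError(
                f"step_std must be 0 or in [1e-3, 1e-1], got {self.step_std}"
            )
        if self.alternating_period < 1:
            raise InvalidParameterError("alternating_period must be >= 1")
        if self.n_xi < 1:
            raise InvalidParameterError("n_xi must be >= 1")


@dataclass(frozen=True)
class TraceStep:
    """State after one proposal; ``V_E``/``R`` are the current measured
    values (``None`` when undefined or not required by the objective)."""

    step: int
    accepted: bool
    V_E: float | None
    R: float | None


@dataclass
class OptimizationTrace:
    steps: list[TraceStep]
    final_extra: ExtraLinks
    initial_V_E: float | None
    initial_R: float | None

    @property
    def final_V_E(self) -> float | None:
        return self.steps[-1].V_E if self.steps else self.initial_V_E

    @property
    def final_R(self) -> float | None:
        return self.steps[-1].R if self.steps else self.initial_R

    @property
    def n_accepted(self) -> int:
        return sum(s.accepted for s in self.steps)

    @property
    def acceptance_fraction(self) -> float:
        return self.n_accepted / len(self.steps) if self.steps else 0.0


def _measure_R(W: np.ndarray, rng: np.random.Generator, n_xi: int, percentile: int) -> float:
    S = W.shape[0]
    absc = np.empty(n_xi)
    for k in range(n_xi):
        xi = rng.uniform(0.0, 1.0, S)
        absc[k] = np.max(np.linalg.eigvals(xi[:, None] * W).real)
    return robustness_R(absc, percentile)


class _Evaluator:
    """Measure (V_E, R) for a weight vector on fixed link locations.

    ``need_R=False`` skips the robustness estimate (the expensive part)
    when only explorability is being optimized.
    """

    def __init__(self, topo, extra0, cfg, rng):
        self.topo = topo
        self.positions = extra0.positions
        self.cfg = cfg
        self.rng = rng

    def __call__(self, weights, need_R: bool):
        extra = ExtraLinks(positions=self.positions, weights=weights)
        res = scan_marginal_homogeneous(self.topo, extra, self.cfg.alpha_value)
        if not res.single_crossing:
            return None, None
        if not need_R:
            return res.V_E, None
        edge = edge_matrix(self.topo, extra, self.cfg.alpha_value)
        r = _measure_R(
            edge.weights.weights, self.rng, self.cfg.n_xi, self.cfg.percentile
        )
        return res.V_E, r


def _improves(objective, v, r, best_v, best_r):
    def gt(new, old):
        if new is None:
            return False
        return True if old is None else new > old

    if objective == "explorability":
        return gt(v, best_v)
    if objective == "robustness":
        return gt(r, best_r)
    if objective == "both":
        return gt(v, best_v) and gt(r, best_r)
    raise InvalidParameterError(objective)


def _climb(topo, extra0, cfg, objective_at_step):
    rng = np.random.default_rng(cfg.seed)
    evaluate = _Evaluator(topo, extra0, cfg, rng)
    need_R0 = objective_at_step(0) != "explorability"
    weights = extra0.weights.copy()
    cur_v, cur_r = evaluate(weights, need_R0)
    init_v, init_r = cur_v, cur_r
    steps: list[TraceStep] = []
    for t in range(cfg.steps):
        obj = objective_at_step(t)
        need_R = obj != "explorability"
        if need_R and cur_r is None and cur_v is not None:
            # entering a robustness period: establish the baseline
            cur_v, cur_r = evaluate(weights, True)
        proposal = weights + rng.normal(0.0, cfg.step_std, size=weights.shape)
        v, r = evaluate(proposal, need_R)
        if _improves(obj, v, r, cur_v, cur_r):
            weights, cur_v, cur_r = proposal, v, r
            steps.append(TraceStep(step=t, accepted=True, V_E=v, R=r))
        else:
            steps.append(TraceStep(step=t, accepted=False, V_E=cur_v, R=cur_r))
    return OptimizationTrace(
        steps=steps,
        final_extra=extra0.with_weights(weights),
        initial_V_E=init_v,
        initial_R=init_r,
    )


def hill_climb(
    topo: TreeLikeTopology, extra0: ExtraLinks, cfg: OptimizationConfig
) -> OptimizationTrace:
    """Single-objective stochastic hill climbing of V_E or R."""
    if cfg.objective not in ("explorability", "robustness"):
        raise InvalidParameterError(
            "hill_climb requires objective 'explorability' or 'robustness'"
        )
    return _climb(topo, extra0, cfg, lambda t: cfg.objective)


def multi_objective_climb(
    topo: TreeLikeTopology, extra0: ExtraLinks, cfg: OptimizationConfig
) -> OptimizationTrace:
    """Joint optimization: mode ``both`` accepts a proposal only when
    V_E and R increase simultaneously; mode ``alternating`` optimizes
    one quantity at a time in periods of ``alternating_period`` steps."""
    if cfg.objective == "both":
        return _climb(topo, extra0, cfg, lambda t: "both")
    if cfg.objective == "alternating":
        period = cfg.alternating_period

        def pick(t):
            return "explorability" if (t // period) % 2 == 0 else "robustness"

        return _climb(topo, extra0, cfg, pick)
    raise InvalidParameterError(
        "multi_objective_climb requires objective 'both' or 'alternating'"
    )


def evaluate_network(
    topo: TreeLikeTopology,
    extra: ExtraLinks,
    n_xi: int = 2000,
    seed=None,
    percentile: int = 5,
    alpha_value: float = 1.0,
) -> tuple[float | None, float | None]:
    """Full-sampling (V_E, R) of a fixed network, for final reporting
    and cross-network comparisons (use a shared seed for paired ones)."""
    res = scan_marginal_homogeneous(topo, extra, alpha_value)
    if not res.single_crossing:
        return None, None
    try:
        edge = edge_matrix(topo, extra, alpha_value)
    except NotApplicableError:  # pragma: no cover
        return res.V_E, None
    rng = np.random.default_rng(seed)
    return res.V_E, _measure_R(edge.weights.weights, rng, n_xi, percentile)
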