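"""Explorability: inverse-weight solving, marginal-stability scans and
distributions of the explorability score.

For a fixed topology the tunable tree weights are recovered from a
target fixed point x* via the row-wise inverse problem
``sum_j w_ij x*_j = -alpha_i``.  Sweeping the homogeneous fixed point
``x*_i = x*`` typically reveals two regions -- unstable at small x*,
stable at large x* -- separated by a single marginal crossing x*_c, and
the explorability score is ``V_E = V_0 - x*_c`` with ``V_0 = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._exceptions import InvalidParameterError, StructuralError
from .glv_core import InteractionMatrix
from .topology import ExtraLinks, TreeLikeTopology, combined_mask

__all__ = [
    "ExplorabilityResult",
    "ExplorabilityDistribution",
    "HeterogeneityConfig",
    "DEFAULT_GRID",
    "V0",
    "inverse_weights",
    "scan_marginal_homogeneous",
    "analytic_xc_loop",
    "sample_explorability_distribution",
    "explorability_heterogeneous",
]

#: Reference constant from which the marginal abundance is subtracted.
V0 = 1.0

#: Default homogeneous scan grid over (0, V0].
DEFAULT_GRID = np.linspace(1e-3, 1.0, 200)

#: Bisection tolerance on the marginal abundance.
XC_TOL = 1e-6


@dataclass(frozen=True)
class ExplorabilityResult:
    """Outcome of a homogeneous marginal-stability scan.

    ``x_c`` and ``V_E`` are ``None`` unless the scan found the
    single-crossing structure (unstable below, stable above).
    """

    single_crossing: bool
    x_c: float | None = None
    V_E: float | None = None
    V_0: float = V0


@dataclass
class ExplorabilityDistribution:
    """Collection of scan results over random extra-link realizations."""

    results: list[ExplorabilityResult]
    C: float
    sigma_eps: float

    @property
    def n_realizations(self) -> int:
        return len(self.results)

    @property
    def fraction_single_crossing(self) -> float:
        if not self.results:
            return float("nan")
        return sum(r.single_crossing for r in self.results) / len(self.results)

    @property
    def V_E_samples(self) -> np.ndarray:
        return np.array([r.V_E for r in self.results if r.single_crossing])

    @property
    def mean_V_E(self) -> float:
        s = self.V_E_samples
        return float(s.mean()) if s.size else float("nan")


@dataclass(frozen=True)
class HeterogeneityConfig:
    """Sampling plan for the heterogeneous explorability estimate."""

    sigma_alpha: float = 0.1
    sigma_x: float = 0.1
    edge_tolerance: float = 1e-2
    n_alpha_draws: int = 10
    n_x_draws: int = 10

    def __post_init__(self):
        if self.sigma_alpha < 0 or self.sigma_x < 0:
            raise InvalidParameterError("jitter stds must be >= 0")
        if self.edge_tolerance <= 0:
            raise InvalidParameterError("edge_tolerance must be > 0")


def _check_extra_disjoint(topo: TreeLikeTopology, extra: ExtraLinks) -> None:
    if not extra.n_links:
        return
    rows = extra.positions[:, 0]
    cols = extra.positions[:, 1]
    if np.any(topo.successor[rows] == cols):
        raise StructuralError("extra link collides with a base tree link")


def inverse_weights(
    topo: TreeLikeTopology,
    extra: ExtraLinks,
    x_star: np.ndarray,
    alpha,
) -> InteractionMatrix:
    """Recover the weight matrix realizing a target fixed point.

    With the diagonal pinned at -1 and the extra links fixed at their
    strengths, each row has a single tunable entry (its tree link),
    determined exactly by the stationarity condition::

        w_{i, succ(i)} = (x*_i - alpha_i - sum_extra eps_ij x*_j) / x*_{succ(i)}

    so that ``w @ x_star == -alpha`` holds to machine precision.
    """
    S = topo.n_nodes
    x = np.asarray(x_star, dtype=float)
    if x.size != S:
        raise InvalidParameterError("x_star length must equal node count")
    if np.any(x == 0):
        raise InvalidParameterError("x_star components must be nonzero")
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (S,))
    _check_extra_disjoint(topo, extra)

    w = np.zeros((S, S))
    np.fill_diagonal(w, -1.0)
    if extra.n_links:
        w[extra.positions[:, 0], extra.positions[:, 1]] = extra.weights
    extra_dot = np.zeros(S)
    if extra.n_links:
        np.add.at(
            extra_dot, extra.positions[:, 0], extra.weights * x[extra.positions[:, 1]]
        )
    succ = topo.successor
    w[np.arange(S), succ] = (x - a - extra_dot) / x[succ]
    return InteractionMatrix(weights=w, mask=combined_mask(topo, extra))


def _homogeneous_abscissa_fn(topo, extra, alpha_value):
    """Return f(x*) = spectral abscissa of J = x* w(x*) for the
    homogeneous sweep, built once and evaluated many times."""
    S = topo.n_nodes
    base = np.zeros((S, S))
    np.fill_diagonal(base, -1.0)
    if extra.n_links:
        base[extra.positions[:, 0], extra.positions[:, 1]] = extra.weights
    s_row = extra.row_sums(S)
    rows = np.arange(S)
    succ = topo.successor

    def f(x_star: float) -> float:
        w = base.copy()
        w[rows, succ] += 1.0 - alpha_value / x_star - s_row
        return x_star * float(np.max(np.linalg.eigvals(w).real))

    return f


def scan_marginal_homogeneous(
    topo: TreeLikeTopology,
    extra: ExtraLinks | None = None,
    alpha_value: float = 1.0,
    grid: np.ndarray | None = None,
) -> ExplorabilityResult:
    """Sweep the homogeneous fixed point over ``grid``, classify the
    stability sign pattern, and locate the marginal crossing.

    The structure is *single-crossing* when the spectral abscissa is
    positive on an initial segment of the grid and negative on the rest;
    the crossing x*_c is then refined by bisection to ``XC_TOL`` and
    ``V_E = V_0 - x*_c`` is reported.  Any other sign pattern yields
    ``single_crossing=False`` with no score.
    """
    if alpha_value <= 0:
        raise InvalidParameterError("alpha_value must be > 0")
    if extra is None:
        extra = ExtraLinks.empty()
    _check_extra_disjoint(topo, extra)
    g = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    f = _homogeneous_abscissa_fn(topo, extra, alpha_value)
    unstable = np.array([f(x) > 0 for x in g])
    k = int(unstable.sum())
    # single crossing <=> all the unstable points form the initial segment
    if k == 0 or k == g.size or not unstable[:k].all():
        return ExplorabilityResult(single_crossing=False)
    x_c = brentq(f, g[k - 1], g[k], xtol=XC_TOL)
    return ExplorabilityResult(single_crossing=True, x_c=float(x_c), V_E=V0 - float(x_c))


def analytic_xc_loop(L: int) -> float:
    """Closed-form marginal abundance of a bare loop of length ``L``
    (homogeneous case, alpha = 1): 1/2 for even L and
    cos(pi/L) / (1 + cos(pi/L)) for odd L.

    Serves as an independent oracle for the numeric scanner; the L = 3
    loop minimizes x*_c, giving the optimal score V_E = 2/3.
    """
    if L < 2:
        raise InvalidParameterError("loop length must be >= 2")
    if L % 2 == 0:
        return 0.5
    c = math.cos(math.pi / L)
    return c / (1.0 + c)


def sample_explorability_distribution(
    topo: TreeLikeTopology,
    C: float,
    sigma_eps: float,
    n_realizations: int,
    seed=None,
    alpha_value: float = 1.0,
    grid: np.ndarray | None = None,
    return_extras: bool = False,
):
    """Build the explorability distribution P(V_E | C) by drawing random
    extra-link locations and Gaussian weights for each realization.

    Random streams are split per realization from the root seed, so
    results do not depend on evaluation order.
    """
    if n_realizations < 1:
        raise InvalidParameterError("n_realizations must be >= 1")
    from .topology import add_random_links

    children = np.random.SeedSequence(seed).spawn(n_realizations)
    results = []
    extras = []
    for child in children:
        extra = add_random_links(topo, C, sigma_eps, np.random.default_rng(child))
        results.append(scan_marginal_homogeneous(topo, extra, alpha_value, grid))
        if return_extras:
            extras.append(extra)
    dist = ExplorabilityDistribution(results=results, C=C, sigma_eps=sigma_eps)
    return (dist, extras) if return_extras else dist


def explorability_heterogeneous(
    topo: TreeLikeTopology,
    extra: ExtraLinks | None,
    het: HeterogeneityConfig,
    grid: np.ndarray | None = None,
    seed=None,
    alpha: float = 1.0,
) -> np.ndarray:
    """Sample V_E with jittered growth rates and fixed-point components.

    For each draw of growth jitter q (std ``sigma_alpha``) and component
    jitter p (std ``sigma_x``), the base abundance x* sweeps the grid
    with x*_i = x* + p_i held fixed along the sweep; every feasible grid
    point within ``edge_tolerance`` of marginal stability contributes
    one sample ``V_E = 1 - mean(x*_i)``.
    """
    if extra is None:
        extra = ExtraLinks.empty()
    g = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    S = topo.n_nodes
    samples = []
    for _ in range(het.n_alpha_draws):
        q = rng.normal(0.0, het.sigma_alpha, S) if het.sigma_alpha else np.zeros(S)
        for _ in range(het.n_x_draws):
            p = rng.normal(0.0, het.sigma_x, S) if het.sigma_x else np.zeros(S)
            for x_base in g:
                x_vec = x_base + p
                if np.any(x_vec <= 0):
                    continue
                w = inverse_weights(topo, extra, x_vec, alpha + q)
                lam = float(np.max(np.linalg.eigvals(x_vec[:, None] * w.weights).real))
                if abs(lam) < het.edge_tolerance:
                    samples.append(1.0 - float(x_vec.mean()))
    return np.asarray(samples)
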