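"""Dynamical robustness: perturb the dynamics at the edge of stability
and track the spectral abscissa of the reduced Jacobian J'_ij = xi'_i w_ij.

The edge matrix w^edge is the weight matrix whose homogeneous fixed
point sits exactly at the marginal crossing x*_c.  Random perturbations
of the dynamics enter only through the positive vector xi', and the
robustness statistic is R = -(5th percentile of the perturbed abscissa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import InvalidParameterError, NotApplicableError
from .explorability import inverse_weights, scan_marginal_homogeneous
from .glv_core import InteractionMatrix, spectral_abscissa
from .topology import ExtraLinks, TreeLikeTopology, add_random_links

__all__ = [
    "EdgeMatrix",
    "RobustnessSample",
    "edge_matrix",
    "perturbed_abscissa",
    "robustness_R",
    "sample_robustness_distribution",
]


@dataclass(frozen=True)
class EdgeMatrix:
    """Weight matrix at the edge of stability with its marginal
    homogeneous abundance ``x_edge`` (spectral abscissa ~ 0 there)."""

    weights: InteractionMatrix
    x_edge: float


@dataclass
class RobustnessSample:
    """Pooled draws of the perturbed spectral abscissa and the
    percentile-based robustness statistic."""

    abscissas: np.ndarray
    R: float
    percentile: int = 5
    n_eps_total: int = 1
    n_eps_skipped: int = 0

    @property
    def skip_rate(self) -> float:
        return self.n_eps_skipped / self.n_eps_total


def edge_matrix(
    topo: TreeLikeTopology,
    extra: ExtraLinks | None = None,
    alpha_value: float = 1.0,
    grid: np.ndarray | None = None,
) -> EdgeMatrix:
    """Construct w^edge from the homogeneous marginal crossing.

    Raises
    ------
    NotApplicableError
        If the homogeneous scan does not show the single-crossing
        structure (no marginal point is defined).
    """
    if extra is None:
        extra = ExtraLinks.empty()
    res = scan_marginal_homogeneous(topo, extra, alpha_value, grid)
    if not res.single_crossing:
        raise NotApplicableError("no single marginal crossing for this realization")
    S = topo.n_nodes
    x_vec = np.full(S, res.x_c)
    w = inverse_weights(topo, extra, x_vec, alpha_value)
    return EdgeMatrix(weights=w, x_edge=float(res.x_c))


def perturbed_abscissa(edge: EdgeMatrix, xi: np.ndarray) -> float:
    """Spectral abscissa of diag(xi') w^edge for a perturbation xi'."""
    return spectral_abscissa(edge.weights, xi)


def robustness_R(abscissas, percentile: int = 5) -> float:
    """R = -(percentile-th percentile of the abscissa sample), with
    linear interpolation between closest order statistics."""
    a = np.asarray(abscissas, dtype=float)
    if a.size == 0:
        raise InvalidParameterError("empty abscissa sample")
    if not np.all(np.isfinite(a)):
        raise InvalidParameterError("non-finite abscissas")
    return float(-np.percentile(a, percentile, method="linear"))


def sample_robustness_distribution(
    topo: TreeLikeTopology,
    C: float,
    sigma_eps: float,
    n_eps: int,
    n_xi: int,
    seed=None,
    percentile: int = 5,
    alpha_value: float = 1.0,
    grid: np.ndarray | None = None,
    xi_sampler=None,
) -> RobustnessSample:
    """Pool perturbed abscissas over random extra-link configurations.

    For each of ``n_eps`` configurations that admits an edge matrix,
    ``n_xi`` perturbation vectors xi' are drawn (by default i.i.d.
    uniform on [0, 1] per component) and the abscissas are pooled before
    taking the percentile.  Configurations without a single crossing are
    skipped and counted in ``n_eps_skipped``.
    """
    if n_eps < 1 or n_xi < 1:
        raise InvalidParameterError("n_eps and n_xi must be >= 1")
    S = topo.n_nodes
    if xi_sampler is None:
        xi_sampler = lambda rng, size: rng.uniform(0.0, 1.0, size)
    children = np.random.SeedSequence(seed).spawn(n_eps)
    pooled = []
    skipped = 0
    for child in children:
        rng = np.random.default_rng(child)
        extra = add_random_links(topo, C, sigma_eps, rng)
        try:
            edge = edge_matrix(topo, extra, alpha_value, grid)
        except NotApplicableError:
            skipped += 1
            continue
        W = edge.weights.weights
        for _ in range(n_xi):
            xi = xi_sampler(rng, S)
            pooled.append(float(np.max(np.linalg.eigvals(xi[:, None] * W).real)))
    if not pooled:
        raise NotApplicableError("every configuration was skipped")
    abscissas = np.asarray(pooled)
    return RobustnessSample(
        abscissas=abscissas,
        R=robustness_R(abscissas, percentile),
        percentile=percentile,
        n_eps_total=n_eps,
        n_eps_skipped=skipped,
    )
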