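"""Sparse and dense network structures: tree-like topologies, adjacency
masks, and fixed extra links.

A *tree-like* topology is a functional graph: every node has exactly one
off-diagonal outgoing link, so the S off-diagonal links plus the S
self-interactions give connectivity 2S/S**2 = 2/S.  The functional graph
contains exactly one directed cycle; the remaining nodes hang off it as
trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import InvalidParameterError, StructuralError

__all__ = [
    "TreeLikeTopology",
    "AdjacencyMask",
    "ExtraLinks",
    "make_tree_like",
    "add_random_links",
    "connectivity",
    "join_tree_like",
    "merge_sparse_counts",
    "find_cycle",
]


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def find_cycle(successor: np.ndarray) -> list[int]:
    """Return the node list of the unique directed cycle of a functional
    graph given by ``successor`` (out-degree one everywhere).

    Follows the successor map from node 0; the walk must eventually
    repeat a node, and the repeated segment is the cycle reachable from
    node 0.  For a weakly connected functional graph this cycle is the
    unique one.
    """
    successor = np.asarray(successor)
    seen: dict[int, int] = {}
    node = 0
    step = 0
    while node not in seen:
        seen[node] = step
        node = int(successor[node])
        step += 1
    start = seen[node]
    walk = sorted(seen, key=seen.get)
    return walk[start:]


@dataclass(frozen=True)
class TreeLikeTopology:
    """Functional-graph topology: a tree with a single directed loop.

    Attributes
    ----------
    successor
        Integer array of length S; ``successor[i]`` is the unique
        off-diagonal target of node i.
    loop_length
        Length of the unique directed cycle.
    """

    successor: np.ndarray
    loop_length: int

    def __post_init__(self):
        succ = np.asarray(self.successor, dtype=np.intp)
        object.__setattr__(self, "successor", succ)
        S = succ.size
        if S < 2:
            raise InvalidParameterError("need at least 2 nodes")
        if np.any(succ < 0) or np.any(succ >= S):
            raise StructuralError("successor indices out of range")
        if np.any(succ == np.arange(S)):
            raise StructuralError("self-loops are not allowed in the successor map")
        cycle = find_cycle(succ)
        if len(cycle) != self.loop_length:
            raise StructuralError(
                f"declared loop_length {self.loop_length} != detected {len(cycle)}"
            )
        if not self._weakly_connected():
            raise StructuralError("functional graph is not weakly connected")

    def _weakly_connected(self) -> bool:
        S = self.n_nodes
        adj: list[list[int]] = [[] for _ in range(S)]
        for i, j in enumerate(self.successor):
            adj[i].append(int(j))
            adj[int(j)].append(i)
        seen = np.zeros(S, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        return bool(seen.all())

    @property
    def n_nodes(self) -> int:
        return int(self.successor.size)

    def cycle_nodes(self) -> list[int]:
        return find_cycle(self.successor)

    def mask(self) -> "AdjacencyMask":
        """Adjacency mask with the diagonal plus the successor links."""
        S = self.n_nodes
        active = np.zeros((S, S), dtype=bool)
        active[np.diag_indices(S)] = True
        active[np.arange(S), self.successor] = True
        return AdjacencyMask(active=active)


@dataclass(frozen=True)
class AdjacencyMask:
    """Boolean S x S activity mask; the diagonal is always active."""

    active: np.ndarray

    def __post_init__(self):
        active = np.asarray(self.active, dtype=bool)
        object.__setattr__(self, "active", active)
        if active.ndim != 2 or active.shape[0] != active.shape[1]:
            raise InvalidParameterError("mask must be square")
        if not np.all(np.diagonal(active)):
            raise StructuralError("diagonal entries must all be active")

    @property
    def n_nodes(self) -> int:
        return int(self.active.shape[0])


@dataclass(frozen=True)
class ExtraLinks:
    """Fixed-weight links added on top of a base topology.

    ``positions`` is an array of shape (k, 2) of off-diagonal (i, j)
    pairs disjoint from the base links; ``weights`` holds the fixed
    strengths, one per position.
    """

    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.intp).reshape(-1, 2)
        w = np.asarray(self.weights, dtype=float).reshape(-1)
        if pos.shape[0] != w.size:
            raise InvalidParameterError("positions and weights length mismatch")
        if pos.shape[0] and np.any(pos[:, 0] == pos[:, 1]):
            raise StructuralError("extra links may not touch the diagonal")
        if pos.shape[0] != len({(int(i), int(j)) for i, j in pos}):
            raise StructuralError("duplicate extra-link positions")
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("extra-link weights must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "weights", w)

    @property
    def n_links(self) -> int:
        return int(self.positions.shape[0])

    @classmethod
    def empty(cls) -> "ExtraLinks":
        return cls(positions=np.empty((0, 2), dtype=np.intp), weights=np.empty(0))

    def with_weights(self, weights: np.ndarray) -> "ExtraLinks":
        """Same locations, new weights."""
        return ExtraLinks(positions=self.positions.copy(), weights=weights)

    def row_sums(self, n_nodes: int) -> np.ndarray:
        """Sum of extra weights per row (used by the homogeneous scan)."""
        out = np.zeros(n_nodes)
        if self.n_links:
            np.add.at(out, self.positions[:, 0], self.weights)
        return out


def make_tree_like(S: int, loop_length: int, seed=None) -> TreeLikeTopology:
    """Generate a random tree-like topology on ``S`` nodes with a cycle
    of exactly ``loop_length`` nodes.

    An L-cycle is placed on L randomly chosen nodes; every remaining
    node is attached by pointing its successor at a uniformly chosen
    already-placed node, which guarantees connectedness and a unique
    cycle.
    """
    if S < 2:
        raise InvalidParameterError(f"S must be >= 2, got {S}")
    if loop_length < 2 or loop_length > S:
        raise InvalidParameterError(
            f"loop_length must be in [2, S={S}], got {loop_length}"
        )
    rng = _as_rng(seed)
    order = rng.permutation(S)
    cycle = order[:loop_length]
    successor = np.empty(S, dtype=np.intp)
    successor[cycle] = np.roll(cycle, -1)
    placed = list(cycle)
    for node in order[loop_length:]:
        successor[node] = placed[rng.integers(len(placed))]
        placed.append(int(node))
    return TreeLikeTopology(successor=successor, loop_length=loop_length)


def connectivity(mask: AdjacencyMask) -> float:
    """Fraction of active entries among the S**2 possible links,
    self-interactions included."""
    S = mask.n_nodes
    return float(mask.active.sum()) / (S * S)


def combined_mask(topo: TreeLikeTopology, extra: ExtraLinks) -> AdjacencyMask:
    """Mask of the base topology plus extra-link positions."""
    active = topo.mask().active.copy()
    if extra.n_links:
        active[extra.positions[:, 0], extra.positions[:, 1]] = True
    return AdjacencyMask(active=active)


def add_random_links(
    base: TreeLikeTopology,
    target_C: float,
    sigma_eps: float,
    seed=None,
) -> ExtraLinks:
    """Draw extra off-diagonal links with uniformly random locations and
    Gaussian N(0, sigma_eps**2) weights so the union of base and extras
    reaches connectivity ``target_C`` (up to 1/S**2 rounding)."""
    S = base.n_nodes
    if target_C > 1:
        raise InvalidParameterError(f"target_C must be <= 1, got {target_C}")
    n_extra = round(target_C * S * S) - 2 * S
    if n_extra < 0:
        raise InvalidParameterError(
            f"target_C={target_C} below base connectivity 2/S={2 / S}"
        )
    if n_extra == 0:
        return ExtraLinks.empty()
    rng = _as_rng(seed)
    inactive = np.flatnonzero(~base.mask().active.ravel())
    chosen = rng.choice(inactive, size=n_extra, replace=False)
    positions = np.column_stack(np.unravel_index(chosen, (S, S)))
    weights = rng.normal(0.0, sigma_eps, size=n_extra)
    return ExtraLinks(positions=positions, weights=weights)


def join_tree_like(
    a: TreeLikeTopology, b: TreeLikeTopology, seed=None
) -> TreeLikeTopology:
    """Join two tree-like networks into one tree-like network.

    One cycle link of ``a`` is redirected to a node of ``b`` (rather
    than adding a new link), so every node keeps exactly one outgoing
    link; ``a``'s cycle opens into a tree branch and ``b``'s cycle
    becomes the unique cycle of the result.
    """
    rng = _as_rng(seed)
    Sa = a.n_nodes
    successor = np.concatenate([a.successor, b.successor + Sa])
    cycle_a = a.cycle_nodes()
    u = cycle_a[rng.integers(len(cycle_a))]
    successor[u] = Sa + rng.integers(b.n_nodes)
    return TreeLikeTopology(successor=successor, loop_length=b.loop_length)


def merge_sparse_counts(S: int, S_prime: int, a: int, b: int) -> int:
    """Link count after joining two sparse networks with ``a*S - b`` and
    ``a*S' - b`` links using ``b`` links: ``a*(S + S') - b``."""
    if a < 1 or b < 0:
        raise InvalidParameterError("need a >= 1 and b >= 0")
    if a * S - b <= 0 or a * S_prime - b <= 0:
        raise InvalidParameterError("negative or zero link counts")
    return (a * S - b) + (a * S_prime - b) + b
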