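import numpy as np
import networkx as nx
import pytest

from explora.topology import ExtraLinks, TreeLikeTopology, make_tree_like


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_cycle():
    """The explorability-optimal topology: a bare 3-node loop."""
    return TreeLikeTopology(successor=np.array([1, 2, 0]), loop_length=3)


@pytest.fixture
def two_cycle():
    return TreeLikeTopology(successor=np.array([1, 0]), loop_length=2)


@pytest.fixture
def tree6():
    return make_tree_like(6, 3, seed=7)


@pytest.fixture
def no_extras():
    return ExtraLinks.empty()


def assert_tree_like(successor, loop_length):
    """Independent brute-force check of the tree-like invariants using
    networkx: out-degree one, weak connectivity, a unique directed cycle
    of the requested length."""
    successor = np.asarray(successor)
    S = successor.size
    assert np.all(successor != np.arange(S)), "self-loop in successor map"
    G = nx.DiGraph([(i, int(successor[i])) for i in range(S)])
    G.add_nodes_from(range(S))
    assert all(G.out_degree(n) == 1 for n in range(S))
    assert nx.number_weakly_connected_components(G) == 1
    cycles = list(nx.simple_cycles(G))
    assert len(cycles) == 1, f"expected a unique cycle, found {len(cycles)}"
    assert len(cycles[0]) == loop_length


def sensitive_extra_position(topo, eps=0.5, x=None):
    """Find an off-diagonal position whose extra link actually shifts the
    marginal spectrum (closes a directed cycle through the loop); used by
    the optimization tests so single-link climbs have something to climb."""
    from explora.explorability import analytic_xc_loop, inverse_weights

    S = topo.n_nodes
    xc = analytic_xc_loop(topo.loop_length) if x is None else x
    base = topo.mask().active
    best, best_a = None, 0.0
    for i in range(S):
        for j in range(S):
            if base[i, j]:
                continue
            extra = ExtraLinks(positions=np.array([[i, j]]), weights=np.array([eps]))
            w = inverse_weights(topo, extra, np.full(S, xc), np.ones(S))
            a = abs(np.max(np.linalg.eigvals(xc * w.weights).real))
            if a > best_a:
                best, best_a = (i, j), a
    assert best is not None and best_a > 1e-6
    return best
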