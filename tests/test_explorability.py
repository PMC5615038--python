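import math

import numpy as np
import pytest

from explora._exceptions import InvalidParameterError, StructuralError
from explora.explorability import (
    DEFAULT_GRID,
    HeterogeneityConfig,
    analytic_xc_loop,
    explorability_heterogeneous,
    inverse_weights,
    sample_explorability_distribution,
    scan_marginal_homogeneous,
)
from explora.topology import ExtraLinks, TreeLikeTopology, add_random_links, make_tree_like


def brute_force_xc(topo, extra, alpha=1.0, n_grid=2000):
    """Independent oracle: dense-grid eigenvalue scan with the weight
    matrix rebuilt from the generic inverse formula at every point."""
    S = topo.n_nodes
    xs = np.linspace(1e-3, 1.0, n_grid)
    signs = []
    for x in xs:
        w = inverse_weights(topo, extra, np.full(S, x), alpha)
        signs.append(np.max(np.linalg.eigvals(x * w.weights).real) > 0)
    signs = np.asarray(signs)
    k = signs.sum()
    if k == 0 or k == n_grid or not signs[:k].all():
        return None
    return 0.5 * (xs[k - 1] + xs[k])


class TestInverseWeights:
    def test_trivial_fixed_point(self, three_cycle, no_extras):
        w = inverse_weights(three_cycle, no_extras, np.ones(3), np.ones(3))
        # off-diagonal weights vanish: (1-1)/1 = 0
        assert np.allclose(w.weights, -np.eye(3))

    def test_marginal_fixture(self, three_cycle, no_extras):
        w = inverse_weights(three_cycle, no_extras, np.full(3, 1 / 3), np.ones(3))
        assert w.weights[0, 1] == pytest.approx(-2.0)
        assert np.allclose(w.weights @ np.full(3, 1 / 3), -1.0)

    def test_with_extra_link(self, three_cycle):
        # cycle 0->1->2->0; extra (0, 2) with eps = 0.1 at x* = 1/2
        extra = ExtraLinks(positions=np.array([[0, 2]]), weights=np.array([0.1]))
        x = np.full(3, 0.5)
        w = inverse_weights(three_cycle, extra, x, np.ones(3))
        assert w.weights[0, 1] == pytest.approx((0.5 - 1 - 0.05) / 0.5)  # -1.1
        assert np.max(np.abs(w.weights @ x + 1.0)) < 1e-12

    def test_zero_component_rejected(self, three_cycle, no_extras):
        with pytest.raises(InvalidParameterError):
            inverse_weights(three_cycle, no_extras, np.array([1.0, 0.0, 1.0]), 1.0)

    def test_extra_on_base_link_rejected(self, three_cycle):
        extra = ExtraLinks(positions=np.array([[0, 1]]), weights=np.array([0.1]))
        with pytest.raises(StructuralError):
            inverse_weights(three_cycle, extra, np.ones(3), 1.0)

    def test_residual_exact_with_many_extras(self):
        topo = make_tree_like(12, 5, seed=0)
        extra = add_random_links(topo, 0.5, 0.3, seed=1)
        rng = np.random.default_rng(2)
        x = rng.uniform(0.1, 2.0, 12)
        alpha = rng.uniform(0.5, 2.0, 12)
        w = inverse_weights(topo, extra, x, alpha)
        assert np.max(np.abs(w.weights @ x + alpha)) < 1e-12


class TestScanMarginalHomogeneous:
    @pytest.mark.parametrize("S", [3, 5, 10, 20])
    def test_optimal_tree(self, S):
        topo = make_tree_like(S, 3, seed=S)
        res = scan_marginal_homogeneous(topo)
        assert res.single_crossing
        assert res.x_c == pytest.approx(1 / 3, abs=1e-5)
        assert res.V_E == pytest.approx(2 / 3, abs=1e-5)

    def test_two_loop(self, two_cycle):
        res = scan_marginal_homogeneous(two_cycle)
        assert res.x_c == pytest.approx(0.5, abs=1e-5)
        assert res.V_E == pytest.approx(0.5, abs=1e-5)

    def test_zero_weight_extras_match_bare(self):
        topo = make_tree_like(8, 3, seed=4)
        extra = add_random_links(topo, 0.5, 0.1, seed=5)
        zeroed = extra.with_weights(np.zeros(extra.n_links))
        bare = scan_marginal_homogeneous(topo)
        with_zero = scan_marginal_homogeneous(topo, zeroed)
        assert with_zero.x_c == pytest.approx(bare.x_c, abs=1e-9)

    def test_crossing_brackets_sign_change(self):
        topo = make_tree_like(10, 4, seed=8)
        extra = add_random_links(topo, 0.4, 0.1, seed=9)
        res = scan_marginal_homogeneous(topo, extra)
        assert res.single_crossing
        f = lambda x: np.max(
            np.linalg.eigvals(
                x * inverse_weights(topo, extra, np.full(10, x), 1.0).weights
            ).real
        )
        assert f(res.x_c - 1e-3) > 0
        assert f(res.x_c + 1e-3) < 0

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_brute_force(self, seed):
        topo = make_tree_like(8, 3, seed=seed)
        extra = add_random_links(topo, 0.5, 0.15, seed=seed + 50)
        res = scan_marginal_homogeneous(topo, extra)
        oracle = brute_force_xc(topo, extra)
        assert (oracle is None) == (not res.single_crossing)
        if oracle is not None:
            assert res.x_c == pytest.approx(oracle, abs=1e-3)

    def test_invalid_alpha(self, three_cycle):
        with pytest.raises(InvalidParameterError):
            scan_marginal_homogeneous(three_cycle, alpha_value=0.0)


class TestAnalyticXcLoop:
    def test_known_values(self):
        assert analytic_xc_loop(3) == pytest.approx(1 / 3)
        assert analytic_xc_loop(2) == 0.5
        assert analytic_xc_loop(5) == pytest.approx(
            math.cos(math.pi / 5) / (1 + math.cos(math.pi / 5))
        )
        assert analytic_xc_loop(5) == pytest.approx(0.4472, abs=1e-4)

    def test_minimum_at_three(self):
        for S in range(3, 15):
            values = {L: analytic_xc_loop(L) for L in range(2, S + 1)}
            assert min(values, key=values.get) == 3

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            analytic_xc_loop(1)

    @pytest.mark.parametrize("L", range(2, 8))
    def test_oracle_matches_scanner_on_bare_loops(self, L):
        topo = make_tree_like(L, L, seed=0)
        res = scan_marginal_homogeneous(topo)
        assert res.x_c == pytest.approx(analytic_xc_loop(L), abs=1e-5)


class TestSampleDistribution:
    def test_bare_tree_degenerate(self):
        topo = make_tree_like(12, 3, seed=1)
        dist = sample_explorability_distribution(topo, 2 / 12, 0.1, 20, seed=2)
        assert dist.fraction_single_crossing == 1.0
        assert dist.mean_V_E == pytest.approx(2 / 3, abs=1e-5)
        assert np.ptp(dist.V_E_samples) < 1e-9

    def test_reproducible(self):
        topo = make_tree_like(10, 3, seed=1)
        d1 = sample_explorability_distribution(topo, 0.4, 0.1, 10, seed=7)
        d2 = sample_explorability_distribution(topo, 0.4, 0.1, 10, seed=7)
        assert np.array_equal(d1.V_E_samples, d2.V_E_samples)

    def test_small_sigma_concentrates_at_bare_value(self):
        topo = make_tree_like(10, 3, seed=1)
        dist = sample_explorability_distribution(topo, 0.5, 1e-4, 20, seed=3)
        assert dist.fraction_single_crossing == 1.0
        assert np.max(np.abs(dist.V_E_samples - 2 / 3)) < 1e-2

    def test_invalid_count(self):
        topo = make_tree_like(5, 3, seed=1)
        with pytest.raises(InvalidParameterError):
            sample_explorability_distribution(topo, 0.5, 0.1, 0)


class TestHeterogeneous:
    def test_degenerate_jitter_recovers_homogeneous(self):
        topo = make_tree_like(6, 3, seed=2)
        het = HeterogeneityConfig(
            sigma_alpha=0.0, sigma_x=0.0, n_alpha_draws=1, n_x_draws=1
        )
        samples = explorability_heterogeneous(topo, None, het, seed=0)
        assert samples.size > 0
        # edge-tolerance band around x_c = 1/3 maps to V_E near 2/3
        assert np.max(np.abs(samples - 2 / 3)) < 0.05

    def test_small_jitter_mean_near_optimum(self):
        topo = make_tree_like(6, 3, seed=2)
        het = HeterogeneityConfig(n_alpha_draws=5, n_x_draws=5)
        grid = np.linspace(1e-3, 1.0, 100)
        samples = explorability_heterogeneous(topo, None, het, grid=grid, seed=11)
        assert samples.size > 0
        assert abs(samples.mean() - 2 / 3) < 0.1

    def test_zero_tolerance_empty(self):
        topo = make_tree_like(5, 3, seed=2)
        het = HeterogeneityConfig(
            edge_tolerance=1e-12, n_alpha_draws=2, n_x_draws=2
        )
        grid = np.linspace(0.05, 1.0, 40)
        assert explorability_heterogeneous(topo, None, het, grid=grid, seed=0).size == 0

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            HeterogeneityConfig(sigma_alpha=-0.1)
        with pytest.raises(InvalidParameterError):
            HeterogeneityConfig(edge_tolerance=0.0)
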