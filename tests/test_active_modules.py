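"""Aggregate-z active modules: quantile mapping, calibration, recovery."""

import math

import numpy as np
import pytest

from tfnetminer.active_modules import (
    aggregate_z,
    background_calibration,
    node_z,
    search_modules,
    subset_moments,
)
from tfnetminer.network_build import IntegratedNetwork, NodeData
from tfnetminer.synthetic_data import planted_p_network


def phi_inverse_by_bisection(q: float) -> float:
    """Independent oracle for the standard normal quantile via Phi bisection."""

    def phi(x: float) -> float:
        return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))

    lo, hi = -10.0, 10.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if phi(mid) < q:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class TestNodeZ:
    def test_median_maps_to_zero(self):
        assert node_z(0.5) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0228, 0.9772, 0.001, 0.35])
    def test_matches_bisection_oracle(self, p):
        assert node_z(p) == pytest.approx(phi_inverse_by_bisection(1.0 - p), abs=1e-9)

    def test_symmetry(self):
        assert node_z(0.0228) == pytest.approx(-node_z(0.9772))

    def test_out_of_range_rejected(self):
        for bad in (0.0, -0.1, 1.0001, float("nan")):
            with pytest.raises(ValueError):
                node_z(bad)

    def test_p_of_one_is_clipped_finite(self):
        assert np.isfinite(node_z(1.0))


class TestBackgroundCalibration:
    def test_k_one_matches_sample_moments(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=400)
        mu, sd = background_calibration(z, k=1, n_draws=20_000, seed=1)
        assert mu == pytest.approx(z.mean(), abs=0.02)
        assert sd == pytest.approx(z.std(ddof=1), abs=0.02)

    def test_uniform_p_gives_near_zero_mean(self):
        """mu_k tracks sqrt(k) * mean(z); under uniform p the mean z vanishes.

        The amplification by sqrt(k) means the absolute bound is only
        meaningful when sqrt(k)/sqrt(N) is small, hence N = 5000 and k <= 10.
        """
        rng = np.random.default_rng(2)
        z = node_z(rng.uniform(1e-6, 1 - 1e-6, size=5000))
        for k in (1, 3, 10):
            mu, _ = background_calibration(z, k=k, n_draws=10_000, seed=3)
            assert mu == pytest.approx(np.sqrt(k) * z.mean(), abs=0.05)
            assert abs(mu) < 0.1

    def test_degenerate_background_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            background_calibration(np.zeros(50), k=5, n_draws=200, seed=0)

    def test_monte_carlo_agrees_with_closed_form(self):
        rng = np.random.default_rng(4)
        z = rng.normal(0.3, 1.2, size=300)
        for k in (2, 10, 50):
            mu_mc, sd_mc = background_calibration(z, k=k, n_draws=20_000, seed=5)
            mu_cf, sd_cf = subset_moments(z, k)
            assert mu_mc == pytest.approx(mu_cf, abs=0.05)
            assert sd_mc == pytest.approx(sd_cf, rel=0.05)


class TestScoreAlgebra:
    def test_raw_score_definition(self):
        zs = [2.0, 1.0, 3.0]
        assert aggregate_z(zs) == pytest.approx(6.0 / math.sqrt(3.0))

    def test_appending_zero_z_strictly_decreases(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            zs = rng.normal(1.5, 1.0, size=rng.integers(2, 20))
            if aggregate_z(zs) <= 0:
                continue
            assert aggregate_z(np.append(zs, 0.0)) < aggregate_z(zs)


class TestSearchModules:
    def _net_with_pvalues(self, p_map, edges):
        net = IntegratedNetwork()
        for n in p_map:
            net.add_node(n, NodeData(color="up"))
        for a, b in edges:
            net.add_ppi_edge(a, b)
        return net

    def test_isolated_hot_node_is_singleton_module(self):
        p_map = {"Hot": 0.001, "Ca": 0.99, "Cb": 0.99, "Cc": 0.99}
        net = self._net_with_pvalues(p_map, [("Ca", "Cb"), ("Cb", "Cc")])
        modules = search_modules(net, p_map, n_modules=1, seed=0)
        assert modules[0].members == {"Hot"}

    def test_equal_p_gives_zero_corrected_scores(self):
        p_map = {n: 0.4 for n in ("Aa", "Ab", "Ac", "Ad")}
        net = self._net_with_pvalues(
            p_map, [("Aa", "Ab"), ("Ab", "Ac"), ("Ac", "Ad")]
        )
        modules = search_modules(net, p_map, n_modules=2, seed=0)
        assert all(m.corrected_score == pytest.approx(0.0) for m in modules)

    def test_missing_p_value_is_error(self):
        net = self._net_with_pvalues({"Aa": 0.5}, [])
        net.add_node("Ab", NodeData(color="up"))
        with pytest.raises(ValueError, match="without p-values"):
            search_modules(net, {"Aa": 0.5}, seed=0)

    def test_empty_network_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            search_modules(IntegratedNetwork(), {}, seed=0)

    def test_raw_score_identity_on_found_modules(self):
        net, p_values, _ = planted_p_network(n_nodes=120, module_size=10, seed=7)
        for module in search_modules(net, p_values, n_modules=3, max_size=25, seed=7):
            recomputed = aggregate_z([node_z(p_values[n]) for n in module.members])
            assert module.raw_score == pytest.approx(recomputed, abs=1e-9)

    def test_planted_module_recovered_single_seed(self):
        net, p_values, module = planted_p_network(seed=5)
        top = set(search_modules(net, p_values, n_modules=1, max_size=30, seed=5)[0].members)
        jaccard = len(top & module) / len(top | module)
        assert jaccard >= 0.8

    def test_deterministic_given_seed(self):
        net, p_values, _ = planted_p_network(n_nodes=100, module_size=8, seed=9)
        m1 = search_modules(net, p_values, seed=11)
        m2 = search_modules(net, p_values, seed=11)
        assert m1 == m2

    def test_members_connected_in_network(self):
        import networkx as nx

        net, p_values, _ = planted_p_network(n_nodes=150, module_size=12, seed=13)
        g = net.union_graph()
        for module in search_modules(net, p_values, n_modules=3, max_size=25, seed=13):
            assert nx.is_connected(g.subgraph(module.members))
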