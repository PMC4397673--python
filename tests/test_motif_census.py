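"""Colored triad census: canonicalization, oracle equivalence, null soundness."""

import itertools

import numpy as np
import pytest

from tfnetminer.motif_census import (
    canonical_code,
    enumerate_triads,
    motif_zscores,
    randomize,
    sketch,
)
from tfnetminer.network_build import IntegratedNetwork, NodeData
from tfnetminer.synthetic_data import er_mixed_network, planted_motif_network


def naive_census(net: IntegratedNetwork) -> dict[str, int]:
    """Independent oracle: enumerate all node triples; canonicalise by the
    lexicographically smallest textual label matrix over all 6 orderings."""
    nodes = sorted(net.nodes)
    reg = net.reg_edges
    ppi = net.ppi_edges
    counts: dict[str, int] = {}
    for trip in itertools.combinations(nodes, 3):
        labels = []
        for perm in itertools.permutations(trip):
            rows = [
                ",".join("1" if net.nodes[v].color == "up" else "0" for v in perm)
            ]
            for a in perm:
                row = []
                for b in perm:
                    if a == b:
                        row.append("x")
                        continue
                    tag = ""
                    if (a, b) in reg:
                        tag += "r"
                    if (min(a, b), max(a, b)) in ppi:
                        tag += "p"
                    row.append(tag or "-")
                rows.append(",".join(row))
            labels.append(";".join(rows))
        # connectivity on the union graph
        union_pairs = sum(
            1
            for a, b in itertools.combinations(trip, 2)
            if (a, b) in reg or (b, a) in reg or (min(a, b), max(a, b)) in ppi
        )
        if union_pairs < 2:
            continue
        label = min(labels)
        counts[label] = counts.get(label, 0) + 1
    return counts


class TestCanonicalization:
    def test_permutation_invariance_random_triads(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            colors = tuple(rng.integers(0, 2, size=3))
            reg = {
                (a, b)
                for a in range(3)
                for b in range(3)
                if a != b and rng.random() < 0.4
            }
            ppi = {tuple(sorted(p)) for p in itertools.combinations(range(3), 2) if rng.random() < 0.4}
            ref = canonical_code(colors, reg, ppi)
            for perm in itertools.permutations(range(3)):
                inv = [0, 0, 0]
                for new, old in enumerate(perm):
                    inv[old] = new
                c2 = tuple(colors[perm[i]] for i in range(3))
                reg2 = {(inv[a], inv[b]) for a, b in reg}
                ppi2 = {tuple(sorted((inv[a], inv[b]))) for a, b in ppi}
                assert canonical_code(c2, reg2, ppi2) == ref

    def test_sketch_is_readable(self):
        code = canonical_code((1, 1, 0), reg=[(0, 1), (0, 2)], ppi=[(1, 2)])
        text = sketch(code)
        assert "→" in text and "–" in text and "up" in text and "down" in text


class TestEnumeration:
    def test_directed_three_cycle_single_class(self):
        net = IntegratedNetwork()
        for n in "ABC":
            net.add_node(n, NodeData(color="up"))
        net.add_reg_edge("A", "B")
        net.add_reg_edge("B", "C")
        net.add_reg_edge("C", "A")
        census = enumerate_triads(net)
        assert sum(census.values()) == 1
        assert list(census.values()) == [1]

    def test_star_co_regulation_counts_leaf_pairs(self):
        net = IntegratedNetwork()
        for n in "ABCD":
            net.add_node(n, NodeData(color="up"))
        for leaf in "BCD":
            net.add_reg_edge("A", leaf)
        census = enumerate_triads(net)
        assert sum(census.values()) == 3  # C(3,2) leaf pairs
        assert len(census) == 1

    def test_fewer_than_three_nodes_empty(self):
        net = IntegratedNetwork()
        net.add_node("A", NodeData(color="up"))
        net.add_node("B", NodeData(color="up"))
        net.add_ppi_edge("A", "B")
        assert enumerate_triads(net) == {}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle_on_random_graphs(self, seed):
        net = er_mixed_network(n=14, p_reg=0.12, p_ppi=0.12, seed=seed)
        census = enumerate_triads(net)
        oracle = naive_census(net)
        assert sum(census.values()) == sum(oracle.values())
        assert sorted(census.values()) == sorted(oracle.values())


class TestRandomize:
    def _degrees(self, net):
        out_deg, in_deg, ppi_deg = {}, {}, {}
        for n in net.nodes:
            out_deg[n] = in_deg[n] = ppi_deg[n] = 0
        for a, b in net.reg_edges:
            out_deg[a] += 1
            in_deg[b] += 1
        for a, b in net.ppi_edges:
            ppi_deg[a] += 1
            ppi_deg[b] += 1
        return out_deg, in_deg, ppi_deg

    def test_degree_sequences_preserved(self):
        net = er_mixed_network(n=25, p_reg=0.1, p_ppi=0.1, seed=1)
        rnd = randomize(net, n_swaps_factor=10, seed=2)
        assert self._degrees(rnd) == self._degrees(net)
        assert {n: d.color for n, d in rnd.nodes.items()} == {
            n: d.color for n, d in net.nodes.items()
        }
        # switching actually moved something on a graph this size
        assert rnd.reg_edges != net.reg_edges or rnd.ppi_edges != net.ppi_edges

    def test_single_edge_layer_unchanged(self):
        net = IntegratedNetwork()
        for n in "AB":
            net.add_node(n, NodeData(color="up"))
        net.add_reg_edge("A", "B")
        rnd = randomize(net, seed=0)
        assert rnd.reg_edges == {("A", "B")}


class TestZScores:
    def test_planted_pattern_flagged(self):
        net, planted = planted_motif_network(n_copies=40, seed=1)
        census = motif_zscores(net, n_random=200, seed=1)
        row = census.table.loc[planted]
        assert row["z_score"] >= 2.0
        assert row["p_empirical"] == 0.0
        assert bool(row["is_motif"])

    def test_counts_conserved_and_classes_real_only(self):
        net = er_mixed_network(n=20, p_reg=0.1, p_ppi=0.1, seed=3)
        census = motif_zscores(net, n_random=20, seed=3)
        real = enumerate_triads(net)
        assert census.table["count_real"].sum() == sum(real.values())
        assert set(census.table.index) == set(real)

    def test_n_random_validation(self, star_network):
        with pytest.raises(ValueError):
            motif_zscores(star_network, n_random=1)
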