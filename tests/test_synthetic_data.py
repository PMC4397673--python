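"""Planted-truth generator: determinism, containment, calibration."""

import numpy as np
import pytest
from scipy import stats

from tfnetminer.diffexpr import call_de
from tfnetminer.enrichment import tf_enrich
from tfnetminer.synthetic_data import (
    PlantedTruth,
    planted_clique_ppi,
    planted_p_network,
    simulate_study,
    write_study,
)


class TestSimulateStudy:
    def test_same_seed_is_bitwise_identical(self):
        a = simulate_study(n_genes=400, n_tfs=40, seed=42)
        b = simulate_study(n_genes=400, n_tfs=40, seed=42)
        assert a.expression.values.equals(b.expression.values)
        assert dict(a.tf_catalog.sets) == dict(b.tf_catalog.sets)
        assert a.ppi_edges == b.ppi_edges
        assert a.truth.de_genes == b.truth.de_genes
        c = simulate_study(n_genes=400, n_tfs=40, seed=43)
        assert not a.expression.values.equals(c.expression.values)

    def test_null_fraction_plants_nothing(self):
        study = simulate_study(n_genes=300, n_tfs=30, de_fraction=0.0, seed=1)
        assert study.truth.de_genes == set()
        assert study.truth.enriched_tfs == set()

    def test_planted_cliques_complete_in_ppi(self):
        for seed in range(5):
            study = simulate_study(n_genes=400, n_tfs=40, seed=seed)
            edges = set(study.ppi_edges)
            for clique in study.truth.ppi_cliques:
                members = sorted(clique)
                for i, a in enumerate(members):
                    for b in members[i + 1 :]:
                        assert (a, b) in edges

    def test_up_down_split_near_balanced_and_disjoint(self):
        study = simulate_study(n_genes=1000, n_tfs=50, seed=2)
        truth = study.truth
        assert not truth.de_genes_up & truth.de_genes_down
        assert abs(len(truth.de_genes_up) - len(truth.de_genes_down)) <= 1

    def test_module_nodes_wired_through_enriched_tfs(self):
        study = simulate_study(n_genes=800, n_tfs=60, seed=3)
        truth = study.truth
        assert truth.enriched_tfs <= truth.active_module_nodes
        for gene in truth.active_module_nodes - truth.enriched_tfs:
            assert any(gene in study.tf_catalog[tf] for tf in truth.enriched_tfs)

    def test_expected_de_exceedance_fourfold(self):
        """Monte-Carlo check against the analytic exceedance oracle.

        With shifts |N(log2 4, 0.5)| and group-mean noise sd 0.25*sqrt(2/3),
        P(called at FC>=3) = P(N(lfc_mean, sqrt(0.5^2 + 2*0.25^2/3)) >= log2 3)
        per planted gene (the down case is symmetric).
        """
        lfc_mean, lfc_sd, noise_sd, n_s = 2.0, 0.5, 0.25, 3
        se = np.sqrt(lfc_sd**2 + 2 * noise_sd**2 / n_s)
        p_call = stats.norm.sf(np.log2(3), loc=lfc_mean, scale=se)
        counts = []
        for seed in range(15):
            study = simulate_study(
                n_genes=2000, n_tfs=100, de_fraction=0.1, lfc_mean=lfc_mean, seed=seed
            )
            de = call_de(study.expression, 3.0)
            counts.append(len(de.de_genes))
        expected = 200 * p_call
        assert np.mean(counts) == pytest.approx(expected, rel=0.10)

    def test_infeasible_sizes_raise(self):
        with pytest.raises(ValueError, match="infeasible|module_size"):
            simulate_study(n_genes=100, n_tfs=10, de_fraction=0.05, module_size=50, seed=0)

    def test_write_study_emits_all_files(self, tmp_path):
        study = simulate_study(n_genes=200, n_tfs=20, seed=5)
        write_study(study, tmp_path)
        for name in [
            "expression.tsv",
            "groups.tsv",
            "tf_targets.gmt",
            "ppi.tsv",
            "pathways.gmt",
            "truth.json",
        ]:
            assert (tmp_path / name).exists()
        back = PlantedTruth.from_json(tmp_path / "truth.json")
        assert back.de_genes == study.truth.de_genes
        assert back.ppi_cliques == study.truth.ppi_cliques


class TestPlantedTruthInvariants:
    def test_overlapping_up_down_rejected(self):
        with pytest.raises(ValueError):
            PlantedTruth(
                de_genes_up={"A"},
                de_genes_down={"A"},
                enriched_tfs=set(),
                ppi_cliques=[],
                active_module_nodes=set(),
                seed=0,
            )


class TestBenchmarkGraphs:
    def test_clique_graph_contains_planted_cliques(self):
        net, cliques = planted_clique_ppi(seed=3)
        for clique in cliques:
            members = sorted(clique)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    assert (min(a, b), max(a, b)) in net.ppi_edges

    def test_planted_p_module_is_connected_and_low_p(self):
        import networkx as nx

        net, p_values, module = planted_p_network(n_nodes=120, module_size=10, seed=4)
        g = net.union_graph()
        assert nx.is_connected(g.subgraph(module))
        assert all(p_values[n] <= 0.01 for n in module)
        background = [p for n, p in p_values.items() if n not in module]
        assert np.mean(background) > 0.3  # uniform background, not deflated


class TestMarginalCalibration:
    def test_null_tf_pvalues_uniform_after_randomization(self):
        """With enrichment_boost = 1 the enrichment p-values carry no signal.

        Discrete one-sided p-values are super-uniform by construction, so the
        KS test is applied to the randomized (continuity-corrected) transform
        P(X > k) + U * P(X = k), which is exactly U(0,1) under the null.
        """
        rng = np.random.default_rng(12345)
        pooled = []
        for seed in range(10):
            study = simulate_study(n_tfs=200, enrichment_boost=1.0, seed=seed)
            de = call_de(study.expression)
            table = tf_enrich(
                de.de_genes, study.tf_catalog, set(study.expression.values.index), de=de
            )
            for row in table.itertuples():
                upper_excl = stats.hypergeom.sf(
                    row.overlap, row.n_universe, row.n_targets, row.n_de
                )
                pmf = stats.hypergeom.pmf(row.overlap, row.n_universe, row.n_targets, row.n_de)
                pooled.append(upper_excl + rng.random() * pmf)
        assert stats.kstest(pooled, "uniform").pvalue > 0.01
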