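"""Hypergeometric enrichment: exact-rational oracle, Holm, DE-TF rule."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from tfnetminer.diffexpr import call_de
from tfnetminer.enrichment import (
    holm,
    hypergeom_two_sided,
    hypergeom_upper_tail,
    pathway_enrich,
    tf_enrich,
)
from tfnetminer.io_formats import GeneSetCollection
from tfnetminer.synthetic_data import simulate_study


def exact_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Independent oracle: rational-arithmetic tail sum of the pmf."""
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return float(Fraction(num, comb(N, n)))


def exact_lower_tail(N: int, K: int, n: int, k: int) -> float:
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(max(0, n + K - N), k + 1))
    return float(Fraction(num, comb(N, n)))


class TestKernels:
    def test_zero_overlap_upper_tail_is_one(self):
        assert hypergeom_upper_tail(20, 5, 8, 0) == pytest.approx(1.0)

    def test_frozen_small_example(self):
        # all 5 targets drawn among 8 DE genes of a 20-gene universe
        expected = Fraction(comb(8, 5), comb(20, 5))  # = 56/15504
        assert hypergeom_upper_tail(20, 5, 8, 5) == pytest.approx(float(expected), abs=1e-14)

    def test_matches_rational_oracle_on_small_grid(self):
        for N in (1, 7, 13, 25):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                            exact_upper_tail(N, K, n, k), abs=1e-12
                        )

    def test_monotone_nonincreasing_in_overlap(self):
        ps = [hypergeom_upper_tail(100, 30, 20, k) for k in range(0, 21)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_two_sided_cap_and_direction(self):
        p, direction = hypergeom_two_sided(20, 5, 20, 5)  # query = universe
        assert p == 1.0
        assert direction == "enrichment"
        p_dep, d_dep = hypergeom_two_sided(100, 50, 20, 2)
        assert d_dep == "depletion"
        assert 0 < p_dep < 1


class TestHolm:
    def test_hand_executed_three_set_example(self):
        adjusted = holm([0.01, 0.02, 0.9])
        assert adjusted == pytest.approx([0.03, 0.04, 0.9])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(size=30)
        adj = holm(raw)
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_single_test_identity(self):
        assert holm([0.2]) == pytest.approx([0.2])


class TestTFEnrich:
    def _toy(self):
        universe = {f"G{i}" for i in range(20)}
        de = {f"G{i}" for i in range(8)}
        catalog = GeneSetCollection.from_dict({"Tfa": {f"G{i}" for i in range(5)}})
        return universe, de, catalog

    def test_row_counts_and_p(self):
        universe, de, catalog = self._toy()
        rows = tf_enrich(de, catalog, universe)
        row = rows.iloc[0]
        assert (row.n_universe, row.n_targets, row.n_de, row.overlap) == (20, 5, 8, 5)
        assert row.p_value == pytest.approx(exact_upper_tail(20, 5, 8, 5), abs=1e-12)

    def test_de_tf_requires_both_p_and_fold_change(self, two_group_matrix):
        de_res = call_de(two_group_matrix, fc_threshold=3.0)
        universe = set(de_res.table.index) | {f"G{i}" for i in range(20)}
        de_genes = de_res.de_genes
        catalog = GeneSetCollection.from_dict(
            {"Up1": de_genes, "Flat": de_genes, "Ghost": de_genes}
        )
        rows = tf_enrich(de_genes, catalog, universe, de=de_res, alpha=0.5, tf_fc_threshold=2.0)
        by_tf = rows.set_index("tf")
        assert bool(by_tf.at["Up1", "is_de_tf"])  # enriched and 8-fold change
        assert not bool(by_tf.at["Flat", "is_de_tf"])  # enriched but flat expression
        assert not bool(by_tf.at["Ghost", "is_de_tf"])  # not measured at all

    def test_empty_inputs_are_errors(self):
        universe, de, catalog = self._toy()
        with pytest.raises(ValueError, match="universe"):
            tf_enrich(de, catalog, set())
        with pytest.raises(ValueError, match="DE"):
            tf_enrich(set(), catalog, universe)


class TestPathwayEnrich:
    def test_degenerate_query_equals_universe(self):
        universe = {f"G{i}" for i in range(10)}
        sets = GeneSetCollection.from_dict({"P1": {"G0", "G1"}, "P2": {"G5"}})
        rows = pathway_enrich(universe, sets, universe)
        assert (rows["p_two_sided"] == 1.0).all()
        assert (rows["p_adjusted"] <= 1.0).all()

    def test_single_set_adjustment_identity(self):
        universe = {f"G{i}" for i in range(30)}
        sets = GeneSetCollection.from_dict({"P1": {f"G{i}" for i in range(10)}})
        rows = pathway_enrich({f"G{i}" for i in range(8)}, sets, universe)
        assert rows.at[0, "p_adjusted"] == pytest.approx(rows.at[0, "p_two_sided"])


class TestNullCalibration:
    def test_fraction_significant_near_alpha_without_boost(self):
        """With no planted enrichment the TF p-values are honest: the mean
        fraction at p <= 0.05 sits in the 0.05 +/- 0.02 band over 20 seeds."""
        fracs = []
        for seed in range(20):
            study = simulate_study(n_tfs=200, enrichment_boost=1.0, seed=seed)
            de = call_de(study.expression)
            table = tf_enrich(
                de.de_genes, study.tf_catalog, set(study.expression.values.index), de=de
            )
            fracs.append(float((table["p_value"] <= 0.05).mean()))
        assert abs(float(np.mean(fracs)) - 0.05) <= 0.02
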