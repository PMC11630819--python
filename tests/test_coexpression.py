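import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vnocode import (
    binarize_presence,
    coexpression_truth,
    genomic_colocalization,
    multiplicity_table,
    pairwise_fisher,
    shannon_per_cell,
    simulate_counts,
)
from vnocode._stats import bh_adjust
from vnocode.coexpression import ConfigError
from vnocode.experiments import brute_force_enrichment_p


class TestPresenceThresholding:
    def test_count_threshold_boundary_inclusive(self, counts_factory, small_annotation):
        cm = counts_factory([[9, 10, 11]], ["V1R_001"])
        presence = binarize_presence(cm, small_annotation, ["V1R"], min_cells=1)
        assert presence.presence.sum() == 2  # 10 and 11 count, 9 does not

    def test_min_cells_retention(self, counts_factory, small_annotation):
        cm = counts_factory(
            [[10] * 4 + [0], [10] * 5], ["V1R_001", "V1R_002"]
        )
        presence = binarize_presence(cm, small_annotation, ["V1R"])
        assert presence.retained_receptors == ["V1R_002"]
        assert presence.receptor_ids == ["V1R_001", "V1R_002"]  # stays in matrix

    def test_unit_threshold_equals_nonzero_pattern(self, counts_factory, small_annotation):
        mat = np.array([[0, 1, 1], [1, 0, 1]])
        cm = counts_factory(mat, ["V1R_001", "V1R_002"])
        presence = binarize_presence(cm, small_annotation, ["V1R"], count_threshold=1, min_cells=1)
        assert np.array_equal(presence.presence, mat > 0)

    def test_threshold_below_one_rejected(self, counts_factory, small_annotation):
        cm = counts_factory([[1]], ["V1R_001"], ["c0"])
        with pytest.raises(ConfigError):
            binarize_presence(cm, small_annotation, ["V1R"], count_threshold=0)


class TestShannon:
    def test_closed_forms(self, counts_factory, small_annotation):
        cm = counts_factory(
            [[10, 10, 5, 0], [10, 0, 3, 0], [0, 0, 2, 0]],
            ["V1R_001", "V1R_002", "V1R_003"],
        )
        stats = shannon_per_cell(cm, small_annotation, ["V1R"]).set_index("barcode")
        assert stats.loc["c0", "shannon_H"] == pytest.approx(math.log(2))
        assert stats.loc["c1", "shannon_H"] == pytest.approx(0.0)
        # (5, 3, 2): hand evaluation of -sum p ln p
        assert stats.loc["c2", "shannon_H"] == pytest.approx(1.0297, abs=1e-4)
        assert stats.loc["c3", "h_undefined"]

    def test_top_shares_non_increasing(self, counts_factory, small_annotation):
        cm = counts_factory([[5], [3], [2]], ["V1R_001", "V1R_002", "V1R_003"])
        row = shannon_per_cell(cm, small_annotation, ["V1R"]).iloc[0]
        assert row["top1_share"] >= row["top2_share"] >= row["top3_share"]
        assert row["top1_share"] + row["top2_share"] + row["top3_share"] <= 1 + 1e-12

    @given(st.lists(st.integers(0, 200), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=60)
    def test_entropy_bounds(self, counts):
        counts = np.array(counts, dtype=float)
        total = counts.sum()
        if total == 0:
            return
        p = counts[counts > 0] / total
        h = -(p * np.log(p)).sum()
        k = (counts > 0).sum()
        assert -1e-12 <= h <= math.log(k) + 1e-12


class TestMultiplicity:
    def test_all_single_receptor(self, counts_factory, small_annotation):
        from vnocode.datatypes import CellRecord

        cm = counts_factory(np.full((1, 10), 10), ["V1R_001"])
        presence = binarize_presence(cm, small_annotation, ["V1R"])
        cells = [CellRecord(f"c{i}", cell_type="mVSN") for i in range(10)]
        table = multiplicity_table(presence, cells)
        row = table.iloc[0]
        assert (row["frac_0"], row["frac_1"], row["frac_2"], row["frac_3plus"]) == (0, 1, 0, 0)

    def test_unknown_group_key_rejected(self, counts_factory, small_annotation):
        cm = counts_factory([[10]], ["V1R_001"], ["c0"])
        presence = binarize_presence(cm, small_annotation, ["V1R"], min_cells=1)
        with pytest.raises(ValueError):
            multiplicity_table(presence, [], group_by=("sex",))

    def test_immature_cells_co_express_more(self):
        # the generator boosts planted co-expression in immature cells
        wins = 0
        for seed in range(20):
            truth = coexpression_truth(seed=seed, co_prob=0.4, immature_multiplier=2.0,
                                       p14_multiplier=1.0)
            sim = simulate_counts(truth, 2500)
            presence = binarize_presence(sim.counts, sim.annotation, ["V1R"])
            table = multiplicity_table(presence, sim.cells).set_index("cell_type")
            multi = table["frac_2"] + table["frac_3plus"]
            wins += multi.loc["iVSN"] > multi.loc["mVSN"]
        assert wins >= 18


class TestPairwiseFisher:
    def make_presence(self, mat, small_annotation, counts_factory):
        ids = [f"V1R_{i + 1:03d}" for i in range(mat.shape[0])]
        cm = counts_factory(np.asarray(mat) * 10, ids)
        return binarize_presence(cm, small_annotation, ["V1R"], min_cells=1)

    def test_disjoint_presence_p_is_one(self, small_annotation, counts_factory):
        mat = np.array([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]])
        presence = self.make_presence(mat, small_annotation, counts_factory)
        (result,) = pairwise_fisher(presence)
        assert result.p_value == pytest.approx(1.0)
        assert result.n11 == 0

    def test_perfect_overlap_p_from_enumeration(self, small_annotation, counts_factory):
        # C(3,3) C(3,0) / C(6,3) = 1/20
        mat = np.array([[1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0]])
        presence = self.make_presence(mat, small_annotation, counts_factory)
        (result,) = pairwise_fisher(presence)
        assert result.p_value == pytest.approx(0.05)
        assert math.isinf(result.odds_ratio)

    def test_matches_enumeration_oracle_on_small_tables(self, small_annotation, counts_factory):
        rng = np.random.default_rng(0)
        for _ in range(30):
            mat = rng.integers(0, 2, size=(3, 12))
            presence = self.make_presence(mat, small_annotation, counts_factory)
            for r in pairwise_fisher(presence):
                expected = brute_force_enrichment_p(
                    r.n11, r.n11 + r.n10, r.n11 + r.n01, r.n_total
                )
                assert r.p_value == pytest.approx(expected, abs=1e-10)

    def test_needs_two_retained_receptors(self, small_annotation, counts_factory):
        cm = counts_factory(np.full((1, 6), 10), ["V1R_001"])
        presence = binarize_presence(cm, small_annotation, ["V1R"])
        with pytest.raises(ConfigError):
            pairwise_fisher(presence)


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        adjusted = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=60)
    def test_bounded_order_preserving_and_never_uncorrecting(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert np.all((adj >= p - 1e-12) & (adj <= 1 + 1e-12))
        assert np.all(bh_adjust(adj) >= adj - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestColocalization:
    def test_no_significant_pairs_flagged_not_zero(self, small_annotation, counts_factory):
        mat = np.array([[1, 1, 0, 0, 1, 0], [0, 0, 1, 1, 0, 1]])
        ids = ["V1R_001", "V1R_002"]
        cm = counts_factory(mat * 10, ids)
        presence = binarize_presence(cm, small_annotation, ["V1R"], min_cells=1)
        results = pairwise_fisher(presence)
        summary = genomic_colocalization(results, small_annotation)
        assert not summary.fraction_defined
        assert math.isnan(summary.fraction_same_chromosome)

    def test_single_chromosome_forces_unit_fraction(self):
        truth = coexpression_truth(seed=2, n_pairs=6, n_same_chromosome=6)
        import dataclasses

        truth = dataclasses.replace(truth, n_chromosomes=1)
        sim = simulate_counts(truth, 1500)
        presence = binarize_presence(sim.counts, sim.annotation, ["V1R"])
        results = pairwise_fisher(presence)
        summary = genomic_colocalization(results, sim.annotation)
        assert summary.fraction_defined
        assert summary.fraction_same_chromosome == 1.0
        assert all(d >= 0 for d in summary.distances_bp.values())
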