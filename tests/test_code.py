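import numpy as np
import pandas as pd
import pytest

from vnocode import (
    SimilarityMatrix,
    block_code_truth,
    build_association,
    generate_receptor_sequences,
    profile_correlation,
    receptor_type_correlation,
    sequence_similarity,
    similarity_relation,
    simulate_counts,
    tf_ag_jaccard,
)
from vnocode.experiments import brute_force_enrichment_p


@pytest.fixture
def wired_dataset():
    truth = block_code_truth(seed=9, n_receptors=12, n_blocks=3)
    sim = simulate_counts(truth, 1200)
    assoc_tf = build_association(sim.counts, sim.annotation, ["V1R"], "TF")
    assoc_ag = build_association(sim.counts, sim.annotation, ["V1R"], "AG")
    return truth, sim, assoc_tf, assoc_ag


class TestAssociation:
    def test_panel_threshold_boundary(self, counts_factory, small_annotation):
        # receptor present in first 3 cells; TF at 2 counts everywhere: never present
        cm = counts_factory(
            [[20, 20, 20, 0, 0, 0], [2, 2, 2, 2, 2, 2]], ["V1R_001", "TF_001"]
        )
        assoc = build_association(cm, small_annotation, ["V1R"], "TF")
        assert assoc.panel_presence.sum() == 0
        assert assoc.p_value.loc["V1R_001", "TF_001"] == pytest.approx(1.0)

    def test_maximal_enrichment_minimizes_row_p(self, counts_factory, small_annotation):
        receptor = [20] * 4 + [0] * 16
        tf_in = [3] * 4 + [0] * 16  # exactly the receptor's cells
        tf_out = [0] * 4 + [3] * 16
        cm = counts_factory([receptor, tf_in, tf_out], ["V1R_001", "TF_001", "TF_002"])
        small_annotation = small_annotation + [
            type(small_annotation[0])("TF_002", small_annotation[5].gene_class, "chr1", 1, 2)
        ]
        assoc = build_association(cm, small_annotation, ["V1R"], "TF")
        row = assoc.p_value.loc["V1R_001"]
        assert row.idxmin() == "TF_001"

    def test_zero_presence_receptor_flagged(self, counts_factory, small_annotation):
        cm = counts_factory([[5, 5], [3, 3]], ["V1R_001", "TF_001"])
        assoc = build_association(cm, small_annotation, ["V1R"], "TF")
        assert assoc.flagged_receptors == ["V1R_001"]
        assert np.isnan(assoc.p_value.loc["V1R_001", "TF_001"])

    def test_p_matches_pair_enumeration_oracle(self, counts_factory, small_annotation):
        rng = np.random.default_rng(3)
        receptor = (rng.random(15) < 0.4) * 20
        tf = (rng.random(15) < 0.5) * 4
        cm = counts_factory(np.array([receptor, tf]), ["V1R_001", "TF_001"])
        assoc = build_association(cm, small_annotation, ["V1R"], "TF")
        n11 = int(((receptor >= 10) & (tf >= 3)).sum())
        ka, kb = int((receptor >= 10).sum()), int((tf >= 3).sum())
        expected = brute_force_enrichment_p(n11, ka, kb, 15)
        assert assoc.p_value.loc["V1R_001", "TF_001"] == pytest.approx(expected, abs=1e-10)

    def test_planted_tf_is_top_association(self, wired_dataset):
        truth, _, assoc_tf, _ = wired_dataset
        hits = sum(
            assoc_tf.p_value.loc[rid].idxmin() in entry.tf_ids
            for rid, entry in truth.code_map.items()
        )
        assert hits >= 0.9 * len(truth.code_map)


class TestProfileCorrelation:
    def make_assoc(self, profiles):
        frame = pd.DataFrame(profiles)
        frame.index = [f"R{i}" for i in range(len(frame))]
        from vnocode.code import AssociationTable
        from vnocode.datatypes import GeneClass

        return AssociationTable(
            panel=GeneClass.TF,
            receptor_ids=list(frame.index),
            panel_ids=list(frame.columns),
            mean_expression=frame,
            p_value=frame * np.nan,
            p_adjusted=frame * np.nan,
            receptor_threshold=10,
            panel_threshold=3,
            cell_barcodes=[],
            receptor_presence=np.zeros((len(frame), 0), bool),
            panel_presence=np.zeros((len(frame.columns), 0), bool),
        )

    def test_identical_profiles_correlate_perfectly(self):
        sim = profile_correlation(self.make_assoc([[1.0, 2, 3], [1.0, 2, 3]]))
        assert sim.values.iloc[0, 1] == pytest.approx(1.0)

    def test_anti_correlated_profiles(self):
        sim = profile_correlation(self.make_assoc([[1.0, 2, 3], [3.0, 2, 1]]))
        assert sim.values.iloc[0, 1] == pytest.approx(-1.0)

    def test_constant_profile_excluded(self):
        sim = profile_correlation(self.make_assoc([[1.0, 2, 3], [5.0, 5, 5], [0.0, 2, 4]]))
        assert sim.excluded == ["R1"]
        assert sim.values.shape == (2, 2)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation(self.make_assoc([[1.0, 1, 1], [2.0, 2, 2]]))

    def test_block_structure_recovered(self, wired_dataset):
        truth, _, assoc_tf, _ = wired_dataset
        sim = profile_correlation(assoc_tf)
        ids = list(sim.values.index)
        order = truth.receptor_ids("V1R")
        block = {r: i * 3 // len(order) for i, r in enumerate(order)}
        within, between = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                (within if block[ids[i]] == block[ids[j]] else between).append(
                    sim.values.iloc[i, j]
                )
        assert np.mean(within) > np.mean(between)


class TestSequenceSimilarity:
    def test_identical_sequences(self):
        sim = sequence_similarity({"a": "MKTAYIAKQR", "b": "MKTAYIAKQR"})
        assert sim.values.loc["a", "b"] == pytest.approx(100.0)
        assert np.allclose(sim.values.values, sim.values.values.T)

    def test_single_substitution_identity(self):
        sim = sequence_similarity({"a": "AAAA", "b": "AATA"})
        assert sim.values.loc["a", "b"] == pytest.approx(75.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_similarity({"a": "", "b": "MK"})

    def test_shuffled_sequence_less_similar(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        below = 0
        for _ in range(100):
            shuffled = "".join(rng.permutation(list(seq)))
            sim = sequence_similarity({"a": seq, "b": shuffled})
            below += sim.values.loc["a", "b"] < 100.0
        assert below >= 95


class TestSimilarityRelation:
    def square(self, mat, ids):
        return SimilarityMatrix("sequence", pd.DataFrame(mat, index=ids, columns=ids))

    def test_identity_relation(self):
        rng = np.random.default_rng(0)
        n = 10
        m = rng.uniform(20, 90, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 100.0)
        ids = [f"R{i}" for i in range(n)]
        rel = similarity_relation(self.square(m, ids), self.square(m.copy(), ids))
        assert rel.spearman_rho == pytest.approx(1.0)
        populated = rel.by_second_bin.dropna()
        assert np.all(populated["mean"] >= populated["bin_lo"] - 1e-9)
        assert np.all(populated["mean"] <= populated["bin_hi"] + 1e-9)

    def test_independent_matrices_uncorrelated(self):
        rng = np.random.default_rng(1)
        n = 50
        ids = [f"R{i}" for i in range(n)]

        def random_sym():
            m = rng.uniform(0, 100, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 100.0)
            return m

        rel = similarity_relation(self.square(random_sym(), ids), self.square(random_sym(), ids))
        assert abs(rel.spearman_rho) < 0.1

    def test_mismatched_receptor_sets_rejected(self):
        a = self.square(np.eye(2) * 100, ["R0", "R1"])
        b = self.square(np.eye(2) * 100, ["R0", "R2"])
        with pytest.raises(ValueError):
            similarity_relation(a, b)

    def test_sequence_clustered_code_gives_positive_spearman(self):
        wins = 0
        for seed in range(10):
            truth = block_code_truth(seed=seed, n_receptors=18, n_blocks=3)
            sim_data = simulate_counts(truth, 1500)
            assoc_ag = build_association(sim_data.counts, sim_data.annotation, ["V1R"], "AG")
            ag_sim = profile_correlation(assoc_ag)
            order = truth.receptor_ids("V1R")
            groups = {r: i * 3 // len(order) for i, r in enumerate(order)}
            seqs = generate_receptor_sequences(order, groups, seed=seed)
            seq_sim = sequence_similarity(seqs)
            common = [r for r in order if r in ag_sim.values.index]
            rel = similarity_relation(
                SimilarityMatrix("sequence", seq_sim.values.loc[common, common]),
                SimilarityMatrix("ag_profile", ag_sim.values.loc[common, common]),
            )
            wins += rel.spearman_rho > 0
        assert wins >= 9


class TestJaccard:
    def test_closed_forms(self, wired_dataset):
        truth, _, assoc_tf, assoc_ag = wired_dataset
        rid = list(truth.code_map)[0]
        grid = tf_ag_jaccard(assoc_tf, assoc_ag, rid)
        assert ((grid.jaccard >= 0) & (grid.jaccard <= 1)).all().all()

    def test_half_overlap(self):
        t = np.array([True, True, True, False])
        a = np.array([False, True, True, True])
        union = (t | a).sum()
        assert (t & a).sum() / union == 0.5  # {c1,c2,c3} vs {c2,c3,c4}

    def test_planted_pairs_out_jaccard_unplanted(self, wired_dataset):
        truth, _, assoc_tf, assoc_ag = wired_dataset
        planted, unplanted = [], []
        for rid, entry in truth.code_map.items():
            other_tfs = [t for t in truth.tf_ids() if t not in entry.tf_ids][:2]
            other_ags = [a for a in truth.ag_ids() if a not in entry.ag_ids][:3]
            grid = tf_ag_jaccard(
                assoc_tf, assoc_ag, rid,
                tf_ids=list(entry.tf_ids) + other_tfs,
                ag_ids=list(entry.ag_ids) + other_ags,
            )
            for t in grid.tf_ids:
                for a in grid.ag_ids:
                    bucket = planted if (t in entry.tf_ids and a in entry.ag_ids) else unplanted
                    bucket.append(float(grid.jaccard.loc[t, a]))
        assert np.mean(planted) > np.mean(unplanted)

    def test_no_significant_partners_gives_flagged_empty_grid(self, counts_factory, small_annotation):
        cm = counts_factory(
            [[20, 20, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]],
            ["V1R_001", "TF_001", "AG_001"],
        )
        assoc_tf = build_association(cm, small_annotation, ["V1R"], "TF")
        assoc_ag = build_association(cm, small_annotation, ["V1R"], "AG")
        grid = tf_ag_jaccard(assoc_tf, assoc_ag, "V1R_001")
        assert grid.empty


class TestReceptorTypeCorrelation:
    def test_duplicate_receptor_profiles_correlate_perfectly(self, wired_dataset):
        truth, _, assoc_tf, assoc_ag = wired_dataset
        combined = receptor_type_correlation(assoc_tf, assoc_ag)
        order = truth.receptor_ids("V1R")
        block = {r: i * 3 // len(order) for i, r in enumerate(order)}
        ids = list(combined.values.index)
        same_block = [
            combined.values.iloc[i, j]
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if block[ids[i]] == block[ids[j]]
        ]
        assert np.mean(same_block) > 0.9

    def test_single_panel_fallback(self, wired_dataset, caplog):
        _, _, assoc_tf, _ = wired_dataset
        with caplog.at_level("WARNING", logger="vnocode"):
            combined = receptor_type_correlation(assoc_tf, None)
        assert combined.kind == "combined"
        assert "one panel empty" in caplog.text

    def test_both_panels_empty_rejected(self):
        with pytest.raises(ValueError):
            receptor_type_correlation(None, None)
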