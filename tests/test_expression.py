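"""Expressed sets, group Venn partitions, breadth classes, heatmap transform."""

import numpy as np
import pandas as pd
import pytest

from splkit.expression import (
    ExpressionMatrix,
    expressed_count_cv,
    expressed_set,
    group_venn,
    heatmap_prep,
    specificity_share,
    tissue_breadth,
)
from splkit.simulate import SimulationConfig, simulate_expression


def _random_matrix(rng, n_transcripts, groups, samples_per_group=2):
    samples, gmap = [], {}
    for g in groups:
        for k in range(samples_per_group):
            sid = f"{g}_s{k}"
            samples.append(sid)
            gmap[sid] = g
    vals = rng.random((n_transcripts, len(samples)))
    vals[rng.random(vals.shape) < 0.5] = 0.0
    ids = [f"t{i}" for i in range(n_transcripts)]
    return ExpressionMatrix(pd.DataFrame(vals, index=ids, columns=samples), gmap)


class TestExpressedSet:
    def test_planted_specific_transcript_only_in_its_group(self):
        cfg = SimulationConfig(
            n_spl=10,
            n_background=0,
            n_samples_per_group={"a": 4, "b": 4},
            block_spec=[],
            specificity_spec={"a": 2},
            dropout_rate=0.3,
            seed=1,
        )
        matrix, truth = simulate_expression(cfg)
        specific = truth[truth.role == "specific"].index
        in_a = expressed_set(matrix, "a")
        in_b = expressed_set(matrix, "b")
        for t in specific:
            assert t in in_a and t not in in_b

    def test_all_zero_transcript_in_no_set(self):
        m = ExpressionMatrix(
            pd.DataFrame([[0.0, 0.0]], index=["z"], columns=["a_s0", "b_s0"]),
            {"a_s0": "a", "b_s0": "b"},
        )
        assert expressed_set(m, "a") == set() and expressed_set(m, "b") == set()

    def test_threshold_above_max_empties_set(self):
        rng = np.random.default_rng(0)
        m = _random_matrix(rng, 5, ["a", "b"])
        assert expressed_set(m, "a", threshold=1e9) == set()

    def test_threshold_monotone(self):
        rng = np.random.default_rng(1)
        m = _random_matrix(rng, 40, ["a", "b"])
        prev = expressed_set(m, "a", 0.0)
        for thr in (0.2, 0.5, 0.9):
            cur = expressed_set(m, "a", thr)
            assert cur <= prev
            prev = cur

    def test_unknown_group_rejected(self):
        rng = np.random.default_rng(2)
        m = _random_matrix(rng, 3, ["a"])
        with pytest.raises(KeyError):
            expressed_set(m, "nope")


class TestGroupVenn:
    def test_engineered_published_age_partition(self, age_venn_matrix):
        venn = group_venn(age_venn_matrix)
        assert venn["per_group"] == {"age5": 42, "age12": 47, "age18": 53, "age25": 64}
        assert venn["intersection"] == 29
        assert venn["specific"] == {"age5": 3, "age12": 3, "age18": 3, "age25": 14}
        assert venn["union"] == 81

    def test_specificity_share_of_oldest_age(self, age_venn_matrix):
        venn = group_venn(age_venn_matrix)
        assert specificity_share(venn["specific"], "age25") == 61

    def test_identical_groups(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0], [2.0, 2.0]], index=["x", "y"],
                         columns=["a_s0", "b_s0"]),
            {"a_s0": "a", "b_s0": "b"},
        )
        venn = group_venn(m)
        assert venn["specific"] == {"a": 0, "b": 0}
        assert venn["intersection"] == venn["union"] == 2

    def test_disjoint_groups(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 0.0], [0.0, 2.0]], index=["x", "y"],
                         columns=["a_s0", "b_s0"]),
            {"a_s0": "a", "b_s0": "b"},
        )
        venn = group_venn(m)
        assert venn["intersection"] == 0
        assert venn["specific"] == venn["per_group"] == {"a": 1, "b": 1}

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_sums_to_union(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_matrix(rng, 50, ["a", "b", "c", "d"])
        venn = group_venn(m)
        assert sum(venn["partition"].values()) == venn["union"]
        # marginal consistency: per-group = sum of cells containing the group
        for g in ("a", "b", "c", "d"):
            total = sum(v for k, v in venn["partition"].items() if g in k)
            assert total == venn["per_group"][g]

    def test_share_input_validation(self):
        with pytest.raises(ValueError):
            specificity_share({"a": 0, "b": 0}, "a")
        with pytest.raises(KeyError):
            specificity_share({"a": 1}, "b")
        assert specificity_share({"a": 1, "b": 0}, "a") == 100
        assert specificity_share({g: 2 for g in "abcd"}, "a") == 25


class TestTissueBreadth:
    def test_engineered_published_breadth(self, tissue_breadth_matrix):
        b = tissue_breadth(tissue_breadth_matrix)
        assert b["expressed"] == 96
        assert b["all_tissues"] == 16
        assert b["one_tissue"] == 9
        assert b["several"] == 71
        assert b["one_tissue_by_tissue"]["fruit_pedicel"] == 5
        assert b["one_tissue_by_tissue"]["leaflet_pedicel"] == 2

    def test_single_ubiquitous_transcript(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0]], index=["x"], columns=["a_s0", "b_s0"]),
            {"a_s0": "a", "b_s0": "b"},
        )
        assert tissue_breadth(m)["all_tissues"] == 1

    def test_empty_matrix(self):
        m = ExpressionMatrix(
            pd.DataFrame([[0.0, 0.0]], index=["x"], columns=["a_s0", "b_s0"]),
            {"a_s0": "a", "b_s0": "b"},
        )
        b = tissue_breadth(m)
        assert b["expressed"] == b["all_tissues"] == b["one_tissue"] == 0


class TestHeatmapPrep:
    def test_zero_variance_row_maps_to_zero(self):
        m = ExpressionMatrix(
            pd.DataFrame([[0.0, 0.0], [1.0, 3.0]], index=["z", "x"],
                         columns=["a_s0", "a_s1"]),
            {"a_s0": "a", "a_s1": "a"},
        )
        out = heatmap_prep(m, row_scale=True)
        assert (out.loc["z"] == 0).all()

    def test_log1p_of_zero_is_zero(self):
        m = ExpressionMatrix(
            pd.DataFrame([[0.0, 1.0]], index=["x"], columns=["a_s0", "a_s1"]),
            {"a_s0": "a", "a_s1": "a"},
        )
        assert heatmap_prep(m).iloc[0, 0] == 0.0

    def test_row_scaling_preserves_ranks(self):
        rng = np.random.default_rng(3)
        m = _random_matrix(rng, 10, ["a"], samples_per_group=6)
        raw = heatmap_prep(m, row_scale=False)
        scaled = heatmap_prep(m, row_scale=True)
        for t in m.transcript_ids:
            if raw.loc[t].std() > 0:
                assert (raw.loc[t].rank() == scaled.loc[t].rank()).all()


class TestGenotypeConsistency:
    def test_cv_over_single_sample_groups(self):
        rng = np.random.default_rng(4)
        m = _random_matrix(rng, 60, [f"cv{i}" for i in range(42)], samples_per_group=1)
        mean, cv = expressed_count_cv(m)
        counts = [len(expressed_set(m, g)) for g in m.group_labels]
        assert mean == pytest.approx(np.mean(counts))
        assert cv == pytest.approx(np.std(counts, ddof=1) / np.mean(counts))


class TestRoundTrip:
    def test_tsv_round_trip_preserves_groups_and_values(self, tmp_path):
        rng = np.random.default_rng(5)
        m = _random_matrix(rng, 8, ["a", "b"])
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = ExpressionMatrix.from_tsv(p)
        assert back.groups == m.groups
        pd.testing.assert_frame_equal(back.values, m.values)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(
                pd.DataFrame([[-1.0]], index=["x"], columns=["a_s0"]), {"a_s0": "a"}
            )
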