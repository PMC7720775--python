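import numpy as np
import pandas as pd
import pytest

from msre_select import assay
from msre_select.io import AssayTable

from .oracles import brute_auc


def small_table(counts_dict, groups, tissues=None):
    samples = list(groups)
    counts = pd.DataFrame(counts_dict, index=samples).T
    meta = pd.DataFrame(
        {
            "group": [groups[s] for s in samples],
            "tissue": [(tissues or {}).get(s, "lung") for s in samples],
        },
        index=samples,
    )
    return AssayTable(counts=counts, metadata=meta)


@pytest.fixture()
def table4():
    groups = {"S1": "normal", "S2": "normal", "S3": "cancer", "S4": "cancer"}
    return small_table(
        {
            "A1": [100, 110, 900, 1000],
            "A2": [9, 10, 11, 9],  # mean 9.75 -> removed
            "A3": [10, 10, 10, 10],  # mean 10 -> retained (strict <)
            "Control1": [1, 0, 2, 0],
            "Control3": [50, 55, 60, 50],
        },
        groups,
    )


class TestFilterLowCount:
    def test_strict_boundary(self, table4):
        filtered, removed = assay.filter_low_count(table4, min_mean=10)
        assert removed == ["A2"]
        assert "A3" in filtered.counts.index

    def test_zero_threshold_is_identity(self, table4):
        filtered, removed = assay.filter_low_count(table4, min_mean=0)
        assert removed == [] and filtered.counts.equals(table4.counts)

    def test_controls_exempt(self, table4):
        filtered, removed = assay.filter_low_count(table4, min_mean=1000)
        assert set(filtered.counts.index) == {"Control1", "Control3"}

    def test_matches_mean_oracle(self, rng):
        groups = {f"S{i}": ("normal" if i % 2 else "cancer") for i in range(6)}
        data = {f"A{i}": list(rng.integers(0, 40, 6)) for i in range(20)}
        data["Control3"] = [50] * 6
        data["Control1"] = [0] * 6
        t = small_table(data, groups)
        _, removed = assay.filter_low_count(t, min_mean=10)
        want = [a for a in data if not a.startswith("Control") and np.mean(data[a]) < 10]
        assert removed == want


class TestNormalize:
    def test_division_by_control(self, table4):
        norm, failed = assay.normalize(table4)
        assert failed == []
        assert norm.loc["A1", "S1"] == pytest.approx(2.0)
        assert (norm.loc["Control3"] == 1.0).all()

    def test_zero_control_sample_flagged_not_divided(self):
        groups = {"S1": "normal", "S2": "normal", "S3": "cancer", "S4": "cancer"}
        t = small_table(
            {"A1": [10, 10, 10, 10], "Control1": [0, 0, 0, 0], "Control3": [5, 0, 5, 5]}, groups
        )
        norm, failed = assay.normalize(t)
        assert failed == ["S2"] and "S2" not in norm.columns

    def test_depth_scale_invariance(self, table4):
        norm1, _ = assay.normalize(table4)
        scaled = table4.counts.copy()
        scaled["S3"] = scaled["S3"] * 7
        t2 = AssayTable(counts=scaled, metadata=table4.metadata)
        norm2, _ = assay.normalize(t2)
        pd.testing.assert_frame_equal(norm1, norm2)


class TestDigestionQC:
    def test_pass_and_fail(self, table4):
        norm, _ = assay.normalize(table4)
        qc = assay.digestion_qc(norm, threshold=0.05)
        assert qc.loc["S2", "pass"] and qc.loc["S4", "pass"]
        qc_strict = assay.digestion_qc(norm, threshold=1e-9)
        assert not qc_strict.loc["S1", "pass"]

    def test_huge_threshold_all_pass(self, table4):
        norm, _ = assay.normalize(table4)
        assert assay.digestion_qc(norm, threshold=1e9)["pass"].all()

    def test_missing_control_errors(self, table4):
        norm, _ = assay.normalize(table4)
        with pytest.raises(ValueError, match="Control9"):
            assay.digestion_qc(norm, control_digest="Control9")


class TestAmpliconStatistics:
    def test_fold_change_without_pseudocount(self):
        groups = {"S1": "normal", "S2": "normal", "S3": "cancer", "S4": "cancer"}
        t = small_table({"A1": [1, 1, 4, 4], "Control3": [1, 1, 1, 1], "Control1": [0, 0, 0, 0]}, groups)
        norm, _ = assay.normalize(t)
        stats = assay.amplicon_statistics(norm.drop(index=["Control1", "Control3"]), t, eps=0.0)
        assert stats.loc["A1", "fold_change"] == pytest.approx(4.0)

    def test_auc_complete_separation(self):
        groups = {"S1": "normal", "S2": "normal", "S3": "cancer", "S4": "cancer"}
        t = small_table({"A1": [10, 20, 80, 90], "Control3": [100] * 4, "Control1": [0] * 4}, groups)
        norm, _ = assay.normalize(t)
        stats = assay.amplicon_statistics(norm.drop(index=["Control1", "Control3"]), t)
        assert stats.loc["A1", "auc"] == 1.0

    def test_constant_zero_amplicon_neutral(self):
        groups = {"S1": "normal", "S2": "normal", "S3": "cancer", "S4": "cancer"}
        t = small_table({"A1": [0, 0, 0, 0], "Control3": [10] * 4, "Control1": [0] * 4}, groups)
        norm, _ = assay.normalize(t)
        stats = assay.amplicon_statistics(norm.drop(index=["Control1", "Control3"]), t)
        assert stats.loc["A1", "auc"] == 0.5
        assert stats.loc["A1", "fold_change"] == pytest.approx(1.0)

    def test_auc_equals_pair_counting_oracle(self, rng):
        for _ in range(30):
            pos = rng.integers(0, 6, size=7).astype(float)
            neg = rng.integers(0, 6, size=5).astype(float)
            assert assay.rank_auc(pos, neg) == pytest.approx(brute_auc(pos, neg))

    def test_q_at_least_p(self, rng):
        groups = {f"S{i}": ("normal" if i < 5 else "cancer") for i in range(10)}
        data = {f"A{i}": list(rng.integers(1, 300, 10)) for i in range(15)}
        data["Control3"] = [100] * 10
        data["Control1"] = [0] * 10
        t = small_table(data, groups)
        norm, _ = assay.normalize(t)
        stats = assay.amplicon_statistics(norm.drop(index=["Control1", "Control3"]), t)
        assert (stats["q"] >= stats["p"] - 1e-15).all()


class TestHeatmapMatrix:
    def _table(self):
        groups = {f"S{i}": ("normal" if i < 3 else "cancer") for i in range(6)}
        tissues = {f"S{i}": t for i, t in enumerate(["lung", "colon", "lung", "colon", "lung", "colon"])}
        data = {
            "A1": [1, 2, 3, 10, 11, 12],
            "A2": [1, 2, 3, 10, 11, 12],  # identical to A1
            "A3": [9, 1, 7, 2, 8, 1],
            "Control3": [1] * 6,
            "Control1": [0] * 6,
        }
        return small_table(data, groups, tissues)

    def test_identical_rows_adjacent(self):
        t = self._table()
        norm, _ = assay.normalize(t)
        mat = assay.export_heatmap_matrix(norm, t, ["A1", "A3", "A2"])
        order = list(mat.index)
        assert abs(order.index("A1") - order.index("A2")) == 1

    def test_sample_order_supervised_and_stable(self, tmp_path):
        t = self._table()
        norm, _ = assay.normalize(t)
        m1 = assay.export_heatmap_matrix(norm, t, ["A1", "A2", "A3"], path=str(tmp_path / "h.tsv"))
        m2 = assay.export_heatmap_matrix(norm, t, ["A1", "A2", "A3"])
        assert list(m1.columns) == list(m2.columns)
        groups = [t.metadata.loc[s, "group"] for s in m1.columns]
        assert groups == sorted(groups)
        assert (tmp_path / "h.tsv").exists()

    def test_empty_selection_rejected(self):
        t = self._table()
        norm, _ = assay.normalize(t)
        with pytest.raises(ValueError):
            assay.export_heatmap_matrix(norm, t, [])
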