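import numpy as np
import pandas as pd
import pytest

from msre_select import dmr
from msre_select.io import Cohort

from .conftest import constant_cohort, make_methylome
from .oracles import brute_region_group_mean


class TestGlobalMethylation:
    def test_count_weighted_mean(self):
        m = make_methylome("s", "normal", [("chr1", 10, 3, 1), ("chr1", 20, 0, 4)])
        assert dmr.global_methylation(m) == pytest.approx(3 / 8)

    def test_fully_methylated(self):
        m = make_methylome("s", "normal", [("chr1", 10, 5, 0), ("chr1", 20, 2, 0)])
        assert dmr.global_methylation(m) == 1.0

    def test_no_coverage_errors(self):
        m = make_methylome("s", "normal", [("chr1", 10, 0, 0)])
        with pytest.raises(ValueError, match="no covered"):
            dmr.global_methylation(m)

    def test_equals_brute_sum(self, rng):
        recs = [
            ("chr1", int(p), int(a), int(b))
            for p, a, b in zip(
                np.sort(rng.choice(10_000, 1000, replace=False)),
                rng.integers(0, 30, 1000),
                rng.integers(0, 30, 1000),
            )
        ]
        m = make_methylome("s", "cancer", recs)
        num = sum(r[2] for r in recs)
        den = sum(r[2] + r[3] for r in recs)
        assert dmr.global_methylation(m) == pytest.approx(num / den)


class TestPairwiseCorrelation:
    def test_diagonal_and_identical_samples(self):
        cohort = constant_cohort(
            {
                "a": ("normal", [0.1, 0.5, 0.9]),
                "b": ("normal", [0.1, 0.5, 0.9]),
                "c": ("cancer", [0.3, 0.3, 0.9]),
                "d": ("cancer", [0.2, 0.1, 0.4]),
            }
        )
        r = dmr.pairwise_correlation(cohort)
        assert np.allclose(np.diag(r), 1.0)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.equals(r.T)

    def test_perfectly_anticorrelated(self):
        cohort = constant_cohort(
            {
                "a": ("normal", [0.1, 0.2, 0.3]),
                "b": ("normal", [0.3, 0.2, 0.1]),
                "c": ("cancer", [0.5, 0.5, 0.5]),
                "d": ("cancer", [0.1, 0.9, 0.1]),
            }
        )
        r = dmr.pairwise_correlation(cohort)
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_insufficient_shared_cpgs_flagged_nan(self):
        a = make_methylome("a", "normal", [("chr1", 10, 1, 1), ("chr1", 20, 1, 1)])
        b = make_methylome("b", "normal", [("chr1", 10, 1, 1), ("chr1", 20, 2, 1)])
        c = make_methylome("c", "cancer", [("chr2", 10, 1, 1), ("chr2", 20, 0, 2)])
        d = make_methylome("d", "cancer", [("chr2", 10, 1, 1), ("chr2", 20, 2, 0)])
        r = dmr.pairwise_correlation(Cohort(samples=[a, b, c, d]))
        assert np.isnan(r.loc["a", "c"])


class TestGroupComparison:
    def test_complete_separation_small_groups_exact(self):
        cohort = constant_cohort(
            {
                "n1": ("normal", [0.1]),
                "n2": ("normal", [0.2]),
                "n3": ("normal", [0.3]),
                "c1": ("cancer", [0.4]),
                "c2": ("cancer", [0.5]),
                "c3": ("cancer", [0.6]),
            }
        )
        u, p = dmr.compare_group_methylation(cohort)
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups_maximal_p(self):
        cohort = constant_cohort(
            {
                "n1": ("normal", [0.4]),
                "n2": ("normal", [0.4]),
                "c1": ("cancer", [0.4]),
                "c2": ("cancer", [0.4]),
            }
        )
        _, p = dmr.compare_group_methylation(cohort)
        assert p == pytest.approx(1.0)

    def test_nine_v_nine_separation_significant(self):
        samples = {f"n{i}": ("normal", [0.6 + 0.01 * i]) for i in range(9)}
        samples |= {f"c{i}": ("cancer", [0.4 + 0.01 * i]) for i in range(9)}
        _, p = dmr.compare_group_methylation(constant_cohort(samples))
        assert p < 0.001

    def test_single_sample_group_rejected(self):
        cohort = constant_cohort(
            {"n1": ("normal", [0.1]), "c1": ("cancer", [0.2]), "c2": ("cancer", [0.3])}
        )
        with pytest.raises(ValueError, match=">=2"):
            dmr.compare_group_methylation(cohort)


class TestBenjaminiHochberg:
    def test_hand_computation(self):
        q = dmr.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert dmr.benjamini_hochberg([0.5]) == pytest.approx([0.5])

    def test_q_at_least_p_and_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            q = dmr.benjamini_hochberg(p)
            assert np.all(q >= p - 1e-15)
            assert np.all(q <= 1.0)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dmr.benjamini_hochberg([0.5, 1.5])


class TestRegionGroupMean:
    def test_single_cpg_two_samples(self):
        cohort = constant_cohort(
            {
                "n1": ("normal", [0.0]),
                "n2": ("normal", [0.03]),
                "c1": ("cancer", [0.5]),
                "c2": ("cancer", [0.5]),
            }
        )
        got = dmr.region_group_mean(cohort, ("chr1", 0, 100), "normal")
        assert got == pytest.approx(0.015)

    def test_unweighted_cpg_mean(self):
        cohort = constant_cohort(
            {
                "n1": ("normal", [0.1, 0.3]),
                "n2": ("normal", [0.1, 0.3]),
                "c1": ("cancer", [0.9, 0.9]),
                "c2": ("cancer", [0.9, 0.9]),
            }
        )
        assert dmr.region_group_mean(cohort, ("chr1", 0, 100), "normal") == pytest.approx(0.2)

    def test_no_cpgs_errors(self):
        cohort = constant_cohort(
            {"n1": ("normal", [0.1]), "n2": ("normal", [0.1]),
             "c1": ("cancer", [0.9]), "c2": ("cancer", [0.9])}
        )
        with pytest.raises(ValueError, match="no eligible"):
            dmr.region_group_mean(cohort, ("chr1", 500, 600), "normal")

    def test_equals_brute_force_double_loop(self, rng):
        samples = {}
        for i in range(3):
            samples[f"n{i}"] = ("normal", list(rng.uniform(0, 1, 8)))
        for i in range(3):
            samples[f"c{i}"] = ("cancer", list(rng.uniform(0, 1, 8)))
        cohort = constant_cohort(samples, coverage=200)
        for group in ("normal", "cancer"):
            got = dmr.region_group_mean(cohort, ("chr1", 0, 60), group)
            want = brute_region_group_mean(cohort, "chr1", 0, 60, group)
            assert got == pytest.approx(want, abs=0.01)  # integer-count rounding


def planted_block_cohort(n_per_group=9, n_cpgs=20, flank=30, delta=0.4):
    """Noiseless cohort: flank CpGs at 0.01 in both groups, a central block
    elevated to 0.01 + delta in every cancer sample."""
    n_total = flank + n_cpgs + flank
    positions = [15 * (i + 1) for i in range(n_total)]
    samples = {}
    block = range(flank, flank + n_cpgs)
    for i in range(n_per_group):
        samples[f"n{i}"] = ("normal", [0.01] * n_total)
        samples[f"c{i}"] = (
            "cancer",
            [0.01 + delta if j in block else 0.01 for j in range(n_total)],
        )
    cohort = constant_cohort(samples, coverage=100, positions=positions)
    start, end = positions[flank], positions[flank + n_cpgs - 1] + 2
    return cohort, (start, end)


class TestCallDmrs:
    def test_no_signal_returns_empty(self):
        samples = {f"n{i}": ("normal", [0.0] * 30) for i in range(3)}
        samples |= {f"c{i}": ("cancer", [0.0] * 30) for i in range(3)}
        assert dmr.call_dmrs(constant_cohort(samples)) == []

    def test_recovers_noiseless_planted_block(self):
        cohort, (start, end) = planted_block_cohort()
        calls = dmr.call_dmrs(cohort)
        assert len(calls) == 1
        rec = calls[0]
        assert rec.direction == "hyper"
        overlap = min(rec.end, end) - max(rec.start, start)
        assert overlap >= 0.9 * (end - start)
        assert rec.q_value < 0.01

    def test_emitted_records_satisfy_all_filters(self, toy_cohort):
        cohort, _ = toy_cohort
        params = dmr.DMRParams()
        for rec in dmr.call_dmrs(cohort, params):
            assert abs(rec.mean_diff) >= params.min_diff
            assert rec.length >= params.min_length_nt
            assert rec.n_cpgs >= params.min_cpgs
            assert rec.q_value < params.q_threshold

    def test_output_sorted_non_overlapping(self, toy_cohort):
        cohort, _ = toy_cohort
        calls = dmr.call_dmrs(cohort)
        by_chrom = {}
        for rec in calls:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        for recs in by_chrom.values():
            for a, b in zip(recs, recs[1:]):
                assert a.end <= b.start

    def test_invariant_to_sample_order(self):
        cohort, _ = planted_block_cohort(n_per_group=4)
        shuffled = Cohort(samples=list(reversed(cohort.samples)))
        a = [(r.chrom, r.start, r.end, round(r.mean_diff, 9)) for r in dmr.call_dmrs(cohort)]
        b = [(r.chrom, r.start, r.end, round(r.mean_diff, 9)) for r in dmr.call_dmrs(shuffled)]
        assert a == b
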