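"""Two-condition deletion calling, run extraction, and summaries."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iedetect import (
    DetectionConfig,
    call_runs,
    candidate_exons,
    detect_sample,
    flanking_condition,
    summarize_samples,
)
from iedetect.deletion_detection import DeletionCall

from conftest import make_gene, make_profile


def brute_force_calls(depths, c1=2.0, c2=10.0, max_window=7, strict=False):
    """Independent oracle: enumerate every contiguous exon interval and test
    both conditions directly with statistics.median."""
    L = len(depths)
    if L < 2:
        return []
    ref = statistics.median(depths)
    if ref == 0:
        return []
    t1, t2 = c1 / 100 * ref, c2 / 100 * ref
    cand = [d < t1 for d in depths]
    flank = [d for d, c in zip(depths, cand) if not c]
    if not flank or not statistics.median(flank) > t2:
        return []
    limit = min(max_window - (1 if strict else 0), L - 1)
    out = []
    for i in range(L):
        for j in range(i, L):
            if (
                all(cand[i : j + 1])
                and (i == 0 or not cand[i - 1])
                and (j == L - 1 or not cand[j + 1])
                and (j - i + 1) <= limit
            ):
                out.append((i + 1, j + 1))
    return out


def _run(depths, **cfg_kwargs):
    config = DetectionConfig(**cfg_kwargs)
    gene = make_gene(len(depths))
    return [(c.first, c.last) for c in call_runs(gene, depths, config)]


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"c1": 0}, {"c1": 10, "c2": 5}, {"c2": 101}, {"max_window": 0},
                   {"threshold_mode": "bogus"}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectionConfig(**kwargs)

    def test_window_limit_semantics(self):
        assert DetectionConfig(max_window=7).window_limit == 7
        assert DetectionConfig(max_window=7, strict_window=True).window_limit == 6


class TestCandidateExons:
    def test_zero_depth_exon_selected(self):
        mask = candidate_exons([50, 50, 50, 50, 0], DetectionConfig())
        assert mask.tolist() == [False, False, False, False, True]

    def test_uniform_gene_has_no_candidates(self):
        assert not candidate_exons([50] * 5, DetectionConfig()).any()

    def test_near_threshold_exon_selected(self):
        # ref median 50, threshold 1.0; 0.9 < 1.0
        mask = candidate_exons([50, 50, 0.9, 50], DetectionConfig())
        assert mask.tolist() == [False, False, True, False]

    def test_tie_at_threshold_is_not_candidate(self):
        mask = candidate_exons([50, 50, 1.0, 50], DetectionConfig())
        assert not mask.any()

    def test_sample_percentile_mode_uses_sample_distribution(self):
        sample = np.array([50.0] * 98 + [0.0, 0.0])
        cfg = DetectionConfig(threshold_mode="sample_percentile", c1=5)
        mask = candidate_exons([50, 0, 50], cfg, sample_depths=sample)
        assert mask.tolist() == [False, True, False]


class TestFlankingCondition:
    def test_healthy_flanks_pass(self):
        depths = [50, 50, 50, 0]
        mask = np.array([False, False, False, True])
        assert flanking_condition(depths, mask, DetectionConfig())

    def test_uniformly_low_gene_rejected_in_sample_mode(self):
        # gene depths ~4 while the rest of the sample sits at 50: the c2-th
        # sample-wide percentile exceeds the flanking median, so no call
        sample = np.array([50.0] * 200 + [4, 4, 4, 0])
        cfg = DetectionConfig(threshold_mode="sample_percentile")
        mask = np.array([False, False, False, True])
        assert not flanking_condition([4, 4, 4, 0], mask, cfg, sample_depths=sample)

    def test_all_candidates_means_no_flank(self):
        mask = np.array([True, True, True])
        assert not flanking_condition([0, 0, 0], mask, DetectionConfig())


class TestCallRuns:
    def test_internal_run_called(self):
        depths = [50.0] * 10
        depths[2:5] = [0, 0, 0]
        assert _run(depths) == [(3, 5)]

    def test_strict_window_suppresses_run_at_limit(self):
        depths = [50.0] * 10
        depths[2:5] = [0, 0, 0]
        assert _run(depths, max_window=3) == [(3, 5)]
        assert _run(depths, max_window=3, strict_window=True) == []

    def test_overlong_run_suppressed_whole_not_truncated(self):
        depths = [50.0] * 20
        depths[2:10] = [0.0] * 8
        assert _run(depths, max_window=7) == []

    def test_whole_gene_deletion_not_called(self):
        assert _run([0.0] * 6) == []

    def test_single_exon_gene_never_called(self):
        gene = make_gene(1)
        assert call_runs(gene, [0.0], DetectionConfig()) == []

    def test_run_of_length_l_minus_one_on_two_exon_gene(self):
        assert _run([0.0, 50.0]) == [(1, 1)]

    def test_zero_median_gene_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            assert _run([0, 0, 0, 50, 0]) == []
        assert "median depth 0" in caplog.text

    def test_two_separate_runs_both_called(self):
        depths = [0, 50, 50, 0, 0, 50, 50, 50]
        assert _run(depths) == [(1, 1), (4, 5)]

    def test_depth_vector_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="depths"):
            call_runs(make_gene(4), [50, 50, 50], DetectionConfig())

    def test_call_metadata(self):
        gene = make_gene(6, gene_id="GX")
        depths = [50, 50, 0, 0, 50, 50]
        (call,) = call_runs(gene, depths, DetectionConfig(), sample_id="s9")
        assert call.sample_id == "s9"
        assert (call.first, call.last, call.run_length) == (3, 4, 2)
        assert call.start == gene.exons[2].start and call.end == gene.exons[3].end
        assert call.reference_depth == 50.0
        assert call.run_depth == 0.0 and call.flanking_depth == 50.0


class TestNoCrossGeneState:
    def test_runs_never_cross_gene_boundary(self):
        """A candidate at the end of one gene and the start of the next stay
        two independent length-1 calls, never one length-2 run."""
        import pandas as pd

        pa = make_profile([50, 50, 0], gene_id="A").table
        pb = make_profile([0, 50, 50], gene_id="B").table
        pb["start"] += 10_000
        pb["end"] += 10_000
        table = pd.concat([pa, pb], ignore_index=True)
        from iedetect import SampleDepthProfile

        profile = SampleDepthProfile(sample_id="s1", table=table)
        profile.table["corrected"] = profile.table["raw_median"]
        genes = [make_gene(3, gene_id="A"), make_gene(3, gene_id="B")]
        calls = detect_sample(profile, genes, DetectionConfig())
        assert {(c.gene_id, c.first, c.last) for c in calls} == {
            ("A", 3, 3),
            ("B", 1, 1),
        }


class TestMonotonicity:
    @given(st.lists(st.integers(0, 100), min_size=2, max_size=12))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_candidate_masks_nest_in_c1(self, depths):
        """Raising c1 can only add condition-1 candidates, never drop one."""
        prev = np.zeros(len(depths), dtype=bool)
        for c1 in (1.0, 2.0, 5.0, 9.0):
            mask = candidate_exons(depths, DetectionConfig(c1=c1))
            assert (mask | prev).tolist() == mask.tolist()
            prev = mask

    @given(st.lists(st.integers(0, 100), min_size=2, max_size=12))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_total_calls_nondecreasing_in_window(self, depths):
        gene = make_gene(len(depths))
        counts = []
        by_length_prev: dict = {}
        for w in range(1, 10):
            calls = call_runs(gene, depths, DetectionConfig(max_window=w))
            counts.append(len(calls))
            by_length = {}
            for c in calls:
                by_length[c.run_length] = by_length.get(c.run_length, 0) + 1
            for length, n in by_length_prev.items():
                assert by_length.get(length, 0) == n
            by_length_prev = by_length
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestOracleEquivalence:
    @given(st.lists(st.integers(0, 60), min_size=2, max_size=12),
           st.integers(1, 9))
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_agrees_with_exhaustive_enumeration(self, depths, max_window):
        gene = make_gene(len(depths))
        got = [
            (c.first, c.last)
            for c in call_runs(gene, depths, DetectionConfig(max_window=max_window))
        ]
        assert got == brute_force_calls(depths, max_window=max_window)


class TestSummaries:
    def _call(self, sample, gene, first, last):
        return DeletionCall(
            sample_id=sample, gene_id=gene, chromosome="chr1", first=first,
            last=last, start=0, end=1, run_depth=0, reference_depth=50,
            flanking_depth=50, c1=2, c2=10,
        )

    def test_single_call_histogram(self):
        s = summarize_samples([self._call("s1", "G", 3, 5)], ["s1"], max_length=7)
        hist = s["by_length"].iloc[0]
        assert hist["3"] == 1 and hist.drop("3").sum() == 0

    def test_recurrence_across_samples(self):
        calls = [self._call("s1", "G", 1, 1), self._call("s2", "G", 1, 1)]
        s = summarize_samples(calls, ["s1", "s2"])
        row = s["by_gene"].set_index("gene_id").loc["G"]
        assert row["n_samples"] == 2

    def test_planted_length_histogram(self):
        lengths = [1, 1, 2, 5]
        calls = [
            self._call("s1", f"G{i}", 1, length) for i, length in enumerate(lengths)
        ]
        s = summarize_samples(calls, ["s1"], max_length=7)
        hist = s["by_length"].iloc[0]
        assert hist["1"] == 2 and hist["2"] == 1 and hist["5"] == 1
        assert hist["3"] == 0 and hist["4"] == 0
        assert s["by_sample"].set_index("sample").loc["s1", "n_calls"] == 4
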