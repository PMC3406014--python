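"""Region calling, input-control validation, and empirical FDR."""

import numpy as np
import pytest
from scipy import stats

from bcpseq.calling import (
    CallConfig,
    call_tf_peaks,
    empirical_fdr,
    input_filter,
    poisson_quantile,
    run_sample,
    segment_hm,
)
from bcpseq.io_formats import RegionCall, reads_from_arrays
from bcpseq.model import PosteriorTrack
from bcpseq.preprocess import CountTrack


def mk_post(values, edges=None, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    if edges is None:
        edges = np.arange(len(values) + 1) * 200
    return PosteriorTrack(chrom, np.asarray(edges), values)


def mk_counts(counts, edges=None, mode="hm", window=200, chrom="chr1"):
    counts = np.asarray(counts, dtype=np.int64)
    if edges is None:
        edges = np.arange(len(counts) + 1) * 200
    return CountTrack(chrom, np.asarray(edges), counts, mode, window if mode == "hm" else None)


def uniform_reads(n, span, seed, chrom="chr1"):
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(0, span - 36, n))
    return reads_from_arrays([chrom] * n, starts, starts + 36, ["+"] * n)


class TestPoissonQuantile:
    @pytest.mark.parametrize("mean,q,expected", [(1.0, 0.90, 2), (1.0, 0.5, 1), (1.0, 1e-9, 0), (5.0, 0.99, 11)])
    def test_against_pmf_cumsum_oracle(self, mean, q, expected):
        # oracle: accumulate pmf terms until >= q
        k, acc = 0, stats.poisson.pmf(0, mean)
        while acc < q:
            k += 1
            acc += stats.poisson.pmf(k, mean)
        assert poisson_quantile(mean, q) == k == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_quantile(0.0, 0.9)
        with pytest.raises(ValueError):
            poisson_quantile(1.0, 1.0)


class TestSegmentHm:
    def test_single_island_from_run(self):
        # global mean 1 -> C = 2; run of 6s spans blocks 2..4
        post = mk_post([1, 1, 6, 6, 6, 1])
        counts = mk_counts([1, 1, 1, 1, 1, 1])
        islands = segment_hm(post, counts, q=0.90)
        assert len(islands) == 1
        assert (islands[0].start, islands[0].end) == (400, 1000)
        assert islands[0].mean_level == pytest.approx(6.0)

    def test_all_below_threshold_no_candidates(self):
        post = mk_post([1.0, 1.5, 2.0])
        counts = mk_counts([1, 2, 1])
        assert segment_hm(post, counts, q=0.90) == []

    def test_whole_track_above_threshold_single_island(self):
        post = mk_post([9, 9, 9, 9])
        counts = mk_counts([1, 1, 1, 1])
        islands = segment_hm(post, counts, q=0.90)
        assert len(islands) == 1
        assert (islands[0].start, islands[0].end) == (0, 800)


class TestCallTfPeaks:
    def make_tf(self, values, counts_mean=1):
        n = len(values)
        edges = np.arange(n + 1) * 50
        counts = np.arange(n) % 2 + counts_mean  # alternating, mean ~counts_mean
        return mk_post(values, edges), CountTrack("chr1", edges, counts, "tf")

    def test_subarea_extension_strictly_less_than_one(self):
        post, counts = self.make_tf([3, 9, 10, 9.5, 4])
        peaks = call_tf_peaks(post, counts, q=0.5)
        assert len(peaks) == 1
        pk = peaks[0]
        # max at block 2; left diff |10-9| = 1 stops; right |10-9.5| < 1 extends
        assert (pk.sub_start, pk.sub_end) == (100, 200)
        assert pk.summit == (100 + 150) // 2

    def test_single_block_area(self):
        post, counts = self.make_tf([0.1, 8, 0.1])
        peaks = call_tf_peaks(post, counts, q=0.9)
        assert len(peaks) == 1
        assert (peaks[0].sub_start, peaks[0].sub_end) == (50, 100)

    def test_equal_maxima_leftmost_wins(self):
        post, counts = self.make_tf([0.2, 7, 7, 0.2])
        peaks = call_tf_peaks(post, counts, q=0.9)
        assert peaks[0].summit == (50 + 100) // 2

    def test_hm_track_rejected(self):
        post = mk_post([1, 2, 3])
        counts = mk_counts([1, 2, 3], mode="hm")
        with pytest.raises(ValueError):
            call_tf_peaks(post, counts)


class TestInputFilter:
    def test_strong_enrichment_retained(self):
        cand = RegionCall("chr1", 1000, 2000, mean_level=5.0)
        control = uniform_reads(1000, 100_000, seed=0)
        kept = input_filter([cand], [50], control, "hm", scale=1.0)
        assert len(kept) == 1
        # lambda0 = density * length = 0.01 * 1000 = 10 -> oracle survival
        assert kept[0].pvalue == pytest.approx(float(stats.poisson.sf(49, 10.0)), rel=1e-6)
        assert kept[0].score == pytest.approx(-np.log10(kept[0].pvalue))

    def test_count_equal_to_null_rejected(self):
        cand = RegionCall("chr1", 1000, 2000, mean_level=1.0)
        control = uniform_reads(1000, 100_000, seed=1)
        kept = input_filter([cand], [10], control, "hm", pvalue_cutoff=1e-3, scale=1.0)
        assert kept == []

    def test_zero_local_control_uses_global_floor(self):
        cand = RegionCall("chr1", 0, 1000, mean_level=5.0)
        # control far away from candidate
        control = uniform_reads(100, 10_000, seed=2)
        control["start"] += 50_000
        control["end"] += 50_000
        kept = input_filter([cand], [40], control, "hm", scale=1.0, genome_span=60_000)
        assert len(kept) == 1
        assert kept[0].pvalue > 0.0

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        cands = [
            RegionCall("chr1", int(s), int(s) + 500, mean_level=3.0)
            for s in range(0, 50_000, 5_000)
        ]
        obs = rng.integers(0, 30, len(cands))
        control = uniform_reads(2000, 60_000, seed=4)
        n_loose = len(input_filter(cands, obs, control, "hm", pvalue_cutoff=1e-2))
        n_tight = len(input_filter(cands, obs, control, "hm", pvalue_cutoff=1e-5))
        assert n_tight <= n_loose


class TestPipeline:
    def test_hm_islands_cover_truth(self, hm_dataset):
        from bcpseq import metrics, simulate

        profile, chip, control = hm_dataset
        regions, posts, params, info = run_sample(chip, control, CallConfig(mode="hm"))
        truth = simulate.truth_intervals(profile)
        called_bp, truth_bp, inter = metrics.base_overlap_stats(regions, truth)
        assert inter / truth_bp > 0.9
        assert (called_bp - inter) / called_bp < 0.05
        # regions disjoint and sorted
        for a, b in zip(regions, regions[1:]):
            assert a.end <= b.start

    def test_quantile_monotonicity(self, hm_dataset):
        _, chip, control = hm_dataset
        n_lenient = len(run_sample(chip, control, CallConfig(mode="hm", hm_quantile=0.90))[0])
        n_strict = len(run_sample(chip, control, CallConfig(mode="hm", hm_quantile=0.999))[0])
        assert n_strict <= n_lenient

    def test_validated_regions_beat_their_null_quantile(self, hm_dataset):
        _, chip, control = hm_dataset
        regions, _, _, _ = run_sample(chip, control, CallConfig(mode="hm"))
        assert regions
        for r in regions:
            assert r.chip_count > poisson_quantile(max(r.lambda0, 1e-12), 0.90)

    def test_empty_chip_rejected(self, hm_dataset):
        _, chip, control = hm_dataset
        with pytest.raises(ValueError):
            run_sample(chip.iloc[:0], control, CallConfig(mode="hm"))


class TestEmpiricalFdr:
    def test_identical_samples_give_no_or_all_negative_peaks(self, tf_dataset):
        _, chip, _ = tf_dataset
        overall, curve = empirical_fdr(chip, chip, CallConfig(mode="tf"))
        assert overall is None or overall >= 0.9

    def test_strong_signal_low_fdr(self, tf_dataset):
        _, chip, control = tf_dataset
        overall, curve = empirical_fdr(chip, control, CallConfig(mode="tf"))
        assert overall is not None
        assert overall <= 0.05
        assert len(curve) > 0
        # curve columns: rank ascending, fdr within [0, 1]
        assert np.all(np.diff(curve[:, 0]) == 1)
        assert np.all((curve[:, 2] >= 0) & (curve[:, 2] <= 1))

    def test_no_negative_peaks_curve_identically_zero(self, tf_dataset):
        _, chip, control = tf_dataset
        overall, curve = empirical_fdr(chip, control, CallConfig(mode="tf"))
        if overall == 0.0:
            assert np.all(curve[:, 2] == 0.0)
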