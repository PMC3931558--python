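"""Frequency track, window statistics, interval calling, gap subtraction."""

import numpy as np
import pandas as pd
import pytest

from supmap import mapping
from supmap.mapping import IntervalCall, MappingParams

from oracles import interval_oracle, random_track


def track_from_window_means(means, per_window=5, window=100_000, chrom="I"):
    """Markers evenly spaced, ``per_window`` per tile, at the given mean."""
    rows = []
    for w, m in enumerate(means):
        for j in range(per_window):
            pos = w * window + (j + 1) * window // (per_window + 1)
            rows.append((chrom, pos, m, 18))
    return pd.DataFrame(rows, columns=["chrom", "pos", "freq", "depth"])


def params_100k(**kw):
    defaults = dict(window_size=100_000, min_markers_per_window=3,
                    min_interval_span=50_000)
    defaults.update(kw)
    return MappingParams(**defaults)


class TestMarkerFrequencies:
    def pool_df(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ref_count",
                                         "alt_count", "depth", "freq", "is_marker"])
        return df

    def markers_df(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b"])

    def test_frequency_arithmetic_and_min_depth(self):
        pool = self.pool_df([
            ("I", 100, "A", "T", 9, 9, 18, 0.5, True),
            ("I", 200, "A", "T", 2, 1, 3, 1 / 3, True),   # below min depth
            ("I", 300, "G", "A", 0, 18, 18, 1.0, False),  # novel site, ignored
        ])
        markers = self.markers_df([("I", 100, "A", "T"), ("I", 200, "A", "T"),
                                   ("I", 400, "C", "G")])  # 400 missing from pool
        track, report = mapping.marker_frequencies(pool, markers, min_depth=4)
        assert list(track["pos"]) == [100]
        assert track["freq"].iloc[0] == 0.5
        assert report["n_missing_from_pool"] == 1
        assert report["n_below_min_depth"] == 2

    def test_simulated_recessive_pool_depletion(self, full_e2e):
        track = full_e2e["mapping"]["track"]
        unlinked = track[track["chrom"].isin(["III", "V", "X"])]
        assert abs(unlinked["freq"].mean() - 0.50) < 0.05
        causal = full_e2e["bundle"].causal
        near = track[(track["chrom"] == causal.chrom)
                     & (abs(track["pos"] - causal.position) < 250_000)]
        assert near["freq"].mean() < 0.10


class TestDisplayFilter:
    def test_strictly_above_threshold_retained(self):
        track = pd.DataFrame({"chrom": ["I"] * 3, "pos": [1, 2, 3],
                              "freq": [0.05, 0.21, 0.5], "depth": [18] * 3})
        out = mapping.display_filter(track, 0.20)
        assert list(out["freq"]) == [0.21, 0.5]

    def test_empty_and_identity_cases(self):
        empty = pd.DataFrame(columns=["chrom", "pos", "freq", "depth"])
        assert mapping.display_filter(empty, 0.2).empty
        track = pd.DataFrame({"chrom": ["I"] * 4, "pos": range(4),
                              "freq": [0.5] * 4, "depth": [18] * 4})
        assert len(mapping.display_filter(track, 0.2)) == 4


class TestWindowStats:
    def test_means_match_direct_averaging(self):
        rng = np.random.default_rng(0)
        track = random_track(rng, 3, 100_000)
        params = params_100k(min_markers_per_window=1)
        windows = mapping.window_stats(track, params, {"I": 300_000})
        for row in windows.itertuples():
            sub = track[(track["pos"] >= row.start) & (track["pos"] <= row.end)]
            if len(sub):
                assert row.mean_freq == pytest.approx(sub["freq"].mean())
            assert row.n_markers == len(sub)

    def test_sparse_window_flagged_uninformative(self):
        track = track_from_window_means([0.5], per_window=2)
        windows = mapping.window_stats(track, params_100k(), {"I": 100_000})
        assert not windows["informative"].iloc[0]
        with pytest.warns(UserWarning, match="informative"):
            assert mapping.call_intervals(
                windows, track, "recessive", params_100k()) == []


class TestCallIntervals:
    def test_single_low_run_found(self):
        track = track_from_window_means([0.5, 0.5, 0.05, 0.02, 0.5])
        params = params_100k()
        windows = mapping.window_stats(track, params, {"I": 500_000})
        calls = mapping.call_intervals(windows, track, "recessive", params)
        assert len(calls) == 1
        iv = calls[0]
        assert 200_000 < iv.start < iv.end <= 400_000
        assert iv.mean_freq <= params.absence_threshold

    def test_all_high_track_yields_nothing(self):
        track = track_from_window_means([0.5] * 5)
        params = params_100k()
        windows = mapping.window_stats(track, params, {"I": 500_000})
        assert mapping.call_intervals(windows, track, "recessive", params) == []

    def test_reduction_mode_catches_what_absence_misses(self):
        track = track_from_window_means([0.5, 0.25, 0.22, 0.5])
        params = params_100k()
        windows = mapping.window_stats(track, params, {"I": 400_000})
        assert mapping.call_intervals(windows, track, "recessive", params) == []
        dom = mapping.call_intervals(windows, track, "dominant", params)
        assert len(dom) == 1

    def test_no_informative_windows_warns(self):
        track = pd.DataFrame(columns=["chrom", "pos", "freq", "depth"])
        windows = mapping.window_stats(track, params_100k(), {"I": 300_000})
        with pytest.warns(UserWarning, match="informative"):
            assert mapping.call_intervals(windows, track, "recessive",
                                          params_100k()) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_windows = int(rng.integers(3, 51))
        track = random_track(rng, n_windows, 100_000)
        params = params_100k(merge_gap=int(rng.integers(0, 3)))
        windows = mapping.window_stats(track, params, {"I": n_windows * 100_000})
        got = mapping.call_intervals(windows, track, "recessive", params)
        expected = interval_oracle(windows, track, "recessive", params)
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_lowering_threshold_never_enlarges_intervals(self, seed):
        rng = np.random.default_rng(100 + seed)
        track = random_track(rng, 30, 100_000)
        hi = params_100k(absence_threshold=0.10)
        lo = params_100k(absence_threshold=0.06)
        windows = mapping.window_stats(track, hi, {"I": 3_000_000})
        calls_hi = mapping.call_intervals(windows, track, "recessive", hi)
        calls_lo = mapping.call_intervals(windows, track, "recessive", lo)
        for small in calls_lo:
            assert any(big.start <= small.start and small.end <= big.end
                       for big in calls_hi)


class TestSubtractKnownGaps:
    GAPS = [("I", 1_500_000, 12_800_000), ("IV", 0, 15_800_000)]

    def iv(self, chrom, start, end):
        return IntervalCall(chrom, start, end, 0.02, 50, "recessive")

    def test_interval_inside_gap_flagged_nonunique(self):
        out = mapping.subtract_known_gaps([self.iv("I", 2_000_000, 10_000_000)],
                                          self.GAPS, 500_000)
        assert len(out) == 1 and not out[0].unique

    def test_interval_on_gapless_chromosome_stays_unique(self):
        out = mapping.subtract_known_gaps([self.iv("II", 5_400_000, 7_000_000)],
                                          self.GAPS, 500_000)
        assert out[0].unique
        assert (out[0].start, out[0].end) == (5_400_000, 7_000_000)

    def test_partial_overlap_trimmed_to_residual(self):
        out = mapping.subtract_known_gaps([self.iv("IV", 14_000_000, 17_000_000)],
                                          self.GAPS, 500_000)
        assert out[0].unique
        assert (out[0].start, out[0].end) == (15_800_000, 17_000_000)
        # same residual fails a stricter span requirement
        out2 = mapping.subtract_known_gaps([self.iv("IV", 14_000_000, 17_000_000)],
                                           self.GAPS, 1_500_000)
        assert not out2[0].unique


class TestClassifyOutcome:
    def iv(self, chrom, unique=True):
        return IntervalCall(chrom, 1_000_000, 2_000_000, 0.02, 50, "recessive",
                            unique=unique)

    def test_one_unique_interval_is_extragenic(self):
        outcome, details = mapping.classify_outcome([self.iv("II")], 0)
        assert outcome == "extragenic_mapped"
        assert details["n_unique"] == 1

    def test_no_interval_with_target_hit_is_linked(self):
        outcome, _ = mapping.classify_outcome([self.iv("IV", unique=False)], 1)
        assert outcome == "linked_to_target"

    def test_nothing_found_is_unmapped(self):
        outcome, _ = mapping.classify_outcome([], 0)
        assert outcome == "unmapped"

    def test_multiple_uniques_reported_ambiguous(self):
        outcome, details = mapping.classify_outcome(
            [self.iv("II"), self.iv("III")], 0)
        assert outcome == "ambiguous"
        assert len(details["unique_intervals"]) == 2


class TestMappingParams:
    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            MappingParams(absence_threshold=0.3, reduction_threshold=0.2)
        with pytest.raises(ValueError):
            MappingParams(window_size=0)
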