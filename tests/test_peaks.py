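"""Peak calling, quantification, and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occtile.occupancy import RATIO, OccupancyTrack
from occtile.peaks import (
    DECREASED,
    INCREASED,
    call_peaks,
    quantify_peak,
    rank_peaks,
)

from conftest import channel_track, make_grid, ratio_track


def brute_force_runs(values, cutoff_up, cutoff_down, min_probes):
    """Oracle: explicit scan for maximal qualifying runs (linear, no gaps)."""
    out = []
    for direction, ok in (
        (INCREASED, lambda v: v >= cutoff_up),
        (DECREASED, lambda v: v <= cutoff_down),
    ):
        i = 0
        while i < len(values):
            if ok(values[i]):
                j = i
                while j + 1 < len(values) and ok(values[j + 1]):
                    j += 1
                if j - i + 1 >= min_probes:
                    out.append((direction, i, j))
                i = j + 1
            else:
                i += 1
    return sorted(out)


def called_runs(track, **kw):
    return sorted(
        (p.direction, p.first_probe, p.last_probe) for p in call_peaks(track, **kw)
    )


class TestCallPeaks:
    def test_two_probe_run_called(self):
        track = ratio_track([1, 6, 7, 1])
        peaks = call_peaks(track)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.direction == INCREASED and p.probe_indices == (1, 2)
        assert p.per_probe_ratios == (6.0, 7.0)
        assert (p.start, p.end) == (105, 270)

    def test_single_probe_spike_is_background(self):
        track = ratio_track([1, 9, 1])
        assert call_peaks(track) == []

    def test_decreased_run(self):
        track = ratio_track([0.1, 0.1, 0.1])
        peaks = call_peaks(track)
        assert len(peaks) == 1
        assert peaks[0].direction == DECREASED and peaks[0].n_probes == 3

    def test_inclusive_thresholds(self):
        track = ratio_track([5.0, 5.0, 1.0, 0.2, 0.2])
        dirs = {p.direction for p in call_peaks(track)}
        assert dirs == {INCREASED, DECREASED}

    def test_max_gap_bridges_dips(self):
        track = ratio_track([6, 1, 6, 6, 1])
        assert called_runs(track, max_gap=0) == [(INCREASED, 2, 3)]
        assert called_runs(track, max_gap=1) == [(INCREASED, 0, 3)]

    def test_circular_wrap_merges_runs_at_origin(self):
        track = ratio_track([8, 1, 1, 1, 1, 1, 1, 1, 1, 7], circular=True)
        peaks = call_peaks(track)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.wraps_origin and p.probe_indices == (9, 0)
        assert p.start == 945 and p.end == 60

    def test_linear_grid_never_wraps(self):
        track = ratio_track([8, 1, 1, 1, 1, 1, 1, 1, 1, 7], circular=False)
        assert call_peaks(track) == []

    @settings(derandomize=True, max_examples=300)
    @given(
        st.lists(
            st.sampled_from([0.05, 0.1, 0.2, 0.5, 1.0, 4.9, 5.0, 6.0, 50.0]),
            min_size=1,
            max_size=50,
        ),
        st.integers(min_value=1, max_value=3),
    )
    def test_matches_brute_force_enumeration(self, values, min_probes):
        track = ratio_track(values)
        assert called_runs(track, min_probes=min_probes) == brute_force_runs(
            values, 5.0, 0.2, min_probes
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=50
        )
    )
    def test_monotonic_in_cutoffs_and_no_overlap(self, values):
        track = ratio_track(values)
        for lo_up, hi_up in [(3.0, 5.0), (5.0, 8.0)]:
            loose = {
                i
                for p in call_peaks(track, cutoff_up=lo_up, min_probes=1)
                if p.direction == INCREASED
                for i in p.probe_indices
            }
            strict = {
                i
                for p in call_peaks(track, cutoff_up=hi_up, min_probes=1)
                if p.direction == INCREASED
                for i in p.probe_indices
            }
            assert strict <= loose
        peaks = call_peaks(track)
        for d in (INCREASED, DECREASED):
            spans = sorted(
                (p.first_probe, p.last_probe) for p in peaks if p.direction == d
            )
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 < a2


class TestQuantifyPeak:
    def _peak(self, values, cutoff_up=5.0):
        track = ratio_track(values)
        (peak,) = call_peaks(track, cutoff_up=cutoff_up)
        return peak, track.grid

    @pytest.mark.parametrize(
        "mut, wt, ros, sr",
        [
            ([50, 50], [10, 10], 5.0, 5.0),
            ([30, 90], [10, 10], 6.0, 6.0),
            ([30, 90], [10, 30], 3.0, 3.0),
            ([30, 90], [30, 10], 3.0, 5.0),  # methods diverge on uneven WT
        ],
    )
    def test_combined_level_both_methods(self, mut, wt, ros, sr):
        from occtile.peaks import Peak

        grid = make_grid(2)
        ratios = np.asarray(mut, float) / np.asarray(wt, float)
        peak = Peak(
            probe_indices=(0, 1),
            start=0,
            end=165,
            direction=INCREASED,
            per_probe_ratios=tuple(ratios),
        )
        mt = channel_track(grid, mut)
        wtt = channel_track(grid, wt)
        assert quantify_peak(peak, wtt, mt, "ratio-of-sums").level == pytest.approx(ros)
        assert quantify_peak(peak, wtt, mt, "sum-ratio").level == pytest.approx(sr)

    def test_identity_level(self):
        grid = make_grid(3)
        ch = channel_track(grid, [40, 50, 60])
        track = OccupancyTrack(grid, np.ones(3), RATIO)
        peak = call_peaks(track, cutoff_up=1.0 + 1e-12)  # no peak at ratio 1
        assert peak == []

    def test_zero_wt_sum_rejected(self):
        grid = make_grid(2)
        track = OccupancyTrack(grid, np.array([6.0, 6.0]), RATIO)
        (peak,) = call_peaks(track)
        with pytest.raises(ZeroDivisionError):
            quantify_peak(peak, channel_track(grid, [0, 0]), channel_track(grid, [5, 5]))


class TestRankPeaks:
    def _quantified(self, levels, direction):
        grid = make_grid(2 * len(levels) + 2)
        peaks = []
        for i, lv in enumerate(levels):
            vals = np.ones(grid.count)
            track = OccupancyTrack(grid, vals, RATIO)
            # build a synthetic quantified peak directly
            from occtile.peaks import Peak

            start = grid.starts[2 * i]
            peaks.append(
                Peak(
                    probe_indices=(2 * i, 2 * i + 1),
                    start=start,
                    end=start + 165,
                    direction=direction,
                    per_probe_ratios=(lv, lv),
                    level=lv,
                    method="ratio-of-sums",
                )
            )
        return peaks

    def test_increased_descending(self):
        peaks = self._quantified([5.1, 82.5, 11.0], INCREASED)
        assert [p.level for p in rank_peaks(peaks, INCREASED)] == [82.5, 11.0, 5.1]

    def test_decreased_ascending(self):
        peaks = self._quantified([0.012, 0.10, 0.02], DECREASED)
        assert [p.level for p in rank_peaks(peaks, DECREASED)] == [0.012, 0.02, 0.10]

    def test_ties_break_by_genomic_start(self):
        peaks = self._quantified([7.0, 7.0], INCREASED)
        ranked = rank_peaks(peaks, INCREASED)
        assert ranked[0].start < ranked[1].start
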