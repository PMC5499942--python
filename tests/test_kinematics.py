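"""Tail-kinematics: filtering, bout/peak detection, classification, fast-slow split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from escapekit.kinematics import (
    BoutEvent,
    TailTrace,
    classify_maneuver,
    detect_bout,
    detect_peaks,
    exclude_trial,
    hemi_period_cutoff_frames,
    kinematic_summary,
    smooth_tail_angle,
    split_fast_slow,
)


def brute_force_median(x: np.ndarray, window: int) -> np.ndarray:
    """Independent sliding-median oracle with the centered convention
    [i-w//2, i+(w-1)//2] (even windows extend one frame further left) and
    shrunken edge windows."""
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo = max(0, i - window // 2)
        hi = min(len(x), i + (window - 1) // 2 + 1)
        out[i] = np.median(x[lo:hi])
    return out


def make_trace(angle, fps=1000.0, stim_frame=0, **kw) -> TailTrace:
    return TailTrace(angle=np.asarray(angle, float), fps=fps, stim_frame=stim_frame, **kw)


class TestSmoothTailAngle:
    def test_constant_trace_unchanged(self):
        tr = make_trace(np.full(50, 5.0))
        assert np.allclose(smooth_tail_angle(tr, 10).angle, 5.0)

    @pytest.mark.parametrize("window", [3, 5, 10])
    def test_single_frame_spike_removed(self, window):
        angle = np.zeros(60)
        angle[30] = 30.0
        sm = smooth_tail_angle(make_trace(angle), window).angle
        assert sm[30] == 0.0

    def test_matches_brute_force_oracle_on_random_traces(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(12, 200))
            w = int(rng.integers(1, min(n, 15) + 1))
            x = rng.normal(0, 10, n)
            got = smooth_tail_angle(make_trace(x), w).angle
            assert np.allclose(got, brute_force_median(x, w))

    def test_window_longer_than_trace_errors(self):
        with pytest.raises(ValueError):
            smooth_tail_angle(make_trace(np.zeros(5)), 10)


class TestDetectBout:
    def test_flat_trace_yields_none(self):
        assert detect_bout(make_trace(np.zeros(500), stim_frame=100)) is None

    def test_decaying_sine_bout_bounds(self):
        # 40 Hz sine, 60 deg, movement from frame 500, amplitude linearly
        # decaying to zero by frame 700, at 1000 fps
        n = 1200
        t = np.arange(n)
        env = np.clip((700 - t) / 200.0, 0.0, 1.0) * (t >= 500)
        angle = 60.0 * env * np.sin(2 * np.pi * 40 * (t - 500) / 1000.0)
        bout = detect_bout(make_trace(angle, stim_frame=450))
        assert bout is not None and not bout.truncated
        assert 498 <= bout.start_frame <= 503
        assert 680 <= bout.end_frame <= 730  # within the quiet tail

    def test_bout_truncated_when_trace_ends_moving(self):
        t = np.arange(400)
        angle = 45.0 * np.sin(2 * np.pi * 30 * t / 1000.0) * (t >= 100)
        bout = detect_bout(make_trace(angle, stim_frame=50))
        assert bout is not None and bout.truncated
        assert bout.end_frame == 399


class TestDetectPeaks:
    def test_pure_sine_extrema_count_and_spacing(self):
        # 30 Hz, 45 deg, 1000 fps, 200 ms: 12 alternating extrema ~16.7
        # frames apart
        t = np.arange(200)
        angle = 45.0 * np.sin(2 * np.pi * 30 * t / 1000.0)
        tr = make_trace(angle)
        peaks = detect_peaks(tr, BoutEvent(0, 199))
        assert len(peaks) == 12
        frames = np.array([f for f, _ in peaks])
        assert np.all(np.isin(np.diff(frames), (16, 17)))
        signs = np.sign([a for _, a in peaks])
        assert np.all(signs[::2] == 1) and np.all(signs[1::2] == -1)

    def test_flat_trace_gives_no_peaks(self):
        assert detect_peaks(make_trace(np.zeros(100)), BoutEvent(0, 99)) == []

    def test_min_separation_keeps_earlier_candidate(self):
        # two maxima 1 ms apart at 2000 fps: only the first is accepted
        angle = np.array([0.0, 5.0, 4.0, 6.0, 0.0, 0.0])
        peaks = detect_peaks(make_trace(angle, fps=2000.0), BoutEvent(0, 5))
        assert peaks == [(1, 5.0)]

    def test_matches_brute_force_rules_on_random_oscillations(self):
        # independent oracle: scan raw extrema and apply the rise /
        # separation / alternation rules sequentially
        rng = np.random.default_rng(7)
        fps = 1000.0
        for _ in range(100):
            f = rng.uniform(15, 60)
            amp = rng.uniform(10, 90)
            t = np.arange(300)
            angle = amp * np.sin(2 * np.pi * f * t / fps) + rng.normal(0, 0.05, 300)
            tr = make_trace(angle, fps=fps)
            got = detect_peaks(tr, BoutEvent(0, 299))

            min_sep = 2.0 * fps / 1000.0
            lookback = 5
            exp = []
            last_kind = 0
            for i in range(1, 299):
                if angle[i] > angle[i - 1] and angle[i] > angle[i + 1]:
                    kind = 1
                elif angle[i] < angle[i - 1] and angle[i] < angle[i + 1]:
                    kind = -1
                else:
                    continue
                if abs(angle[i]) < abs(angle[max(0, i - lookback)]) + 1.0:
                    continue
                if exp and i - exp[-1][0] < min_sep:
                    continue
                if exp and kind == last_kind:
                    if abs(angle[i]) > abs(exp[-1][1]):
                        exp[-1] = (i, angle[i])
                    continue
                exp.append((i, angle[i]))
                last_kind = kind
            assert got == exp


class TestClassifyManeuver:
    @pytest.mark.parametrize(
        "amps,expected",
        [
            ([120, -55, 48, -40, 35, -28], "escape"),
            ([15, -14, 15, -13, 14, -14], "slow_swim"),
            ([80], "unclassified"),
            ([30, -28, 29, -27, 28], "unclassified"),  # symmetric but >= 25 deg
        ],
    )
    def test_rule_application(self, amps, expected):
        peaks = [(10 * i, float(a)) for i, a in enumerate(amps)]
        bout = BoutEvent(0, 10 * len(amps))
        assert classify_maneuver(bout, peaks) == expected


class TestKinematicSummary:
    def test_six_peaks_are_three_oscillations(self):
        peaks = [(10 + 10 * i, 30.0 * (-1) ** i) for i in range(6)]
        tr = make_trace(np.zeros(100), fps=650.0)
        s = kinematic_summary(tr, BoutEvent(0, 80), peaks)
        assert s.n_oscillations == 3

    def test_mean_tbf_from_hemi_periods(self):
        # hemi-period of 13 frames at 650 fps -> 650 / 26 = 25 Hz
        peaks = [(13 * i, 20.0 * (-1) ** i) for i in range(5)]
        tr = make_trace(np.zeros(100), fps=650.0)
        s = kinematic_summary(tr, BoutEvent(0, 60), peaks)
        assert s.mean_tbf_hz == pytest.approx(25.0)

    def test_stationary_head_gives_zero_distance_and_speed(self):
        tr = make_trace(np.zeros(100), head_xy=np.zeros((100, 2)))
        s = kinematic_summary(tr, BoutEvent(10, 60), [(20, 30.0), (30, -20.0)])
        assert s.distance_mm == 0.0 and s.speed_mm_s == 0.0

    def test_single_peak_has_null_tbf(self):
        tr = make_trace(np.zeros(100))
        s = kinematic_summary(tr, BoutEvent(10, 60), [(20, 30.0)])
        assert s.mean_tbf_hz is None


class TestExcludeTrial:
    def _trace(self, pre_move=False):
        n, stim = 400, 200
        t = np.arange(n)
        angle = 80.0 * np.sin(2 * np.pi * 40 * (t - stim) / 1000.0) * (t >= stim)
        angle *= np.clip((stim + 150 - t) / 150.0, 0, 1)
        if pre_move:
            angle += 30.0 * np.sin(2 * np.pi * 20 * t / 1000.0) * (t < 100)
        return make_trace(angle, stim_frame=stim)

    def test_pre_stimulus_movement_excluded(self):
        tr = self._trace(pre_move=True)
        peaks = detect_peaks(tr, BoutEvent(1, len(tr.angle) - 1))
        kept, reason = exclude_trial(tr, peaks)
        assert not kept and reason == "pre_stim_movement"

    def test_late_first_peak_excluded(self):
        tr = make_trace(np.zeros(400), stim_frame=200)
        kept, reason = exclude_trial(tr, [(225, 80.0)])  # 25 frames late
        assert not kept and reason == "late_first_peak"

    def test_weak_first_peak_excluded(self):
        tr = make_trace(np.zeros(400), stim_frame=200)
        kept, reason = exclude_trial(tr, [(208, 45.0)])
        assert not kept and reason == "weak_first_peak"

    def test_valid_escape_kept(self):
        tr = self._trace()
        peaks = detect_peaks(tr, BoutEvent(1, len(tr.angle) - 1))
        kept, reason = exclude_trial(tr, peaks)
        assert kept and reason is None


class TestSplitFastSlow:
    def test_cutoff_conversion_650fps_30hz(self):
        assert hemi_period_cutoff_frames(650.0, 30.0) == pytest.approx(650 / 60)

    def test_all_fast_when_short_hemi_periods(self):
        comp = split_fast_slow([8, 8, 8], 650.0)
        assert comp.labels == ["fast", "fast", "fast"]
        assert comp.summaries["slow"]["n_hemi_periods"] == 0

    def test_single_transition_with_post_slow_exclusion(self):
        comp = split_fast_slow([9, 9, 12, 9, 13], 650.0)
        assert comp.labels == ["fast", "fast", "slow", "excluded", "slow"]

    def test_empty_input_gives_empty_component(self):
        comp = split_fast_slow([], 650.0)
        assert comp.labels == [] and comp.summaries["fast"]["mean_tbf_hz"] is None

    @given(
        st.lists(st.floats(min_value=1.0, max_value=40.0), min_size=1, max_size=40)
    )
    @settings(max_examples=200, deadline=None)
    def test_label_completeness_and_duration_summation(self, hemi):
        comp = split_fast_slow(hemi, 650.0)
        assert len(comp.labels) == len(hemi)
        assert set(comp.labels) <= {"fast", "slow", "excluded"}
        # no fast label after the first slow label
        if "slow" in comp.labels:
            first_slow = comp.labels.index("slow")
            assert "fast" not in comp.labels[first_slow:]
        # durations sum to the total inter-peak duration
        total = sum(
            comp.summaries[lab]["duration_ms"] for lab in ("fast", "slow", "excluded")
        )
        assert total == pytest.approx(sum(hemi) / 650.0 * 1000.0)


class TestTailTraceInvariants:
    def test_rejects_nonfinite_angles(self):
        with pytest.raises(ValueError):
            make_trace([0.0, np.nan, 1.0])

    def test_rejects_stim_frame_outside_trace(self):
        with pytest.raises(ValueError):
            make_trace(np.zeros(10), stim_frame=10)

    def test_bout_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            BoutEvent(10, 5)
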