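"""Tail-angle kinematics of larval zebrafish locomotor maneuvers.

A high-speed camera records the tail angle of a larva (head-embedded at
1000 fps or freely swimming at 650 fps) around an acoustic stimulus.  This
module turns one such angle trace into:

* a detected movement bout (start/end frames),
* the alternating tail-angle peaks within the bout,
* a maneuver category (escape vs slow swim),
* per-trial kinematic summaries (duration, distance, speed, oscillation
  count, mean tail-beat frequency),
* trial-exclusion decisions for the escape assay, and
* a decomposition of the bout into its fast (>30 Hz) and slow (<=30 Hz)
  components based on hemi-periods between consecutive peaks.

A hemi-period is the interval between two consecutive peaks and spans half
an oscillation cycle, so an interval of ``h`` frames at ``fps`` frames/s
corresponds to a cycle frequency of ``fps / (2 h)`` Hz.  At 650 fps the
30 Hz cutoff therefore sits at 650/60 ~ 10.83 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TailTrace",
    "BoutEvent",
    "KinematicSummary",
    "CycleComponent",
    "smooth_tail_angle",
    "detect_bout",
    "detect_peaks",
    "classify_maneuver",
    "kinematic_summary",
    "exclude_trial",
    "split_fast_slow",
    "hemi_period_cutoff_frames",
]

#: Default detection thresholds (degrees/frame at the native fps).
START_DIFF_THRESH = 0.08
QUIET_THRESH = 0.1
N_CONFIRM = 3
QUIET_LEN = 20


@dataclass
class TailTrace:
    """One trial's tail-angle time series.

    Parameters
    ----------
    angle
        Signed tail angle in degrees per frame; positive values are bends
        to one lateral side.
    fps
        Acquisition rate in frames per second (1000 for head-embedded,
        650 for freely-swimming assays).
    stim_frame
        Frame index of stimulus onset (0-based; the stimulus occupies this
        frame).
    head_xy
        Optional ``(n, 2)`` head position in mm (freely-swimming assays).
    """

    angle: np.ndarray
    fps: float
    stim_frame: int
    head_xy: np.ndarray | None = None
    larva_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not (0 <= self.stim_frame < len(self.angle)):
            raise ValueError(
                f"stim_frame {self.stim_frame} outside trace of length {len(self.angle)}"
            )
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("tail angle contains non-finite values")
        if self.head_xy is not None:
            self.head_xy = np.asarray(self.head_xy, dtype=float)
            if self.head_xy.shape != (len(self.angle), 2):
                raise ValueError("head_xy must be (n_frames, 2)")


@dataclass
class BoutEvent:
    """Detected movement bounds and accepted tail-angle peaks."""

    start_frame: int
    end_frame: int
    peaks: list[tuple[int, float]] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("start_frame must precede end_frame")
        frames = [f for f, _ in self.peaks]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("peak frames must be strictly increasing")

    @property
    def peak_frames(self) -> np.ndarray:
        return np.array([f for f, _ in self.peaks], dtype=int)

    @property
    def peak_angles(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks], dtype=float)


@dataclass
class KinematicSummary:
    """Per-trial kinematic variables."""

    duration_ms: float
    n_oscillations: float
    mean_tbf_hz: float | None
    category: str
    first_peak_amplitude_deg: float | None
    first_peak_latency_frames: int | None
    distance_mm: float | None = None
    speed_mm_s: float | None = None


@dataclass
class CycleComponent:
    """Fast/slow decomposition of a bout's hemi-periods.

    ``labels`` holds one of ``fast``/``slow``/``excluded`` per hemi-period;
    ``summaries`` maps each label to duration (ms), oscillation count and
    mean tail-beat frequency over that label's hemi-periods.
    """

    hemi_periods: np.ndarray
    labels: list[str]
    summaries: dict[str, dict[str, float | None]]


def smooth_tail_angle(trace: TailTrace, window: int = 10) -> TailTrace:
    """Median-filter the tail angle with a centered sliding window.

    Each sample is replaced by the median of a ``window``-frame window; at
    the edges the window shrinks to the available samples.  Even windows
    extend one frame further to the left than to the right.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(trace.angle):
        raise ValueError(
            f"window {window} exceeds trace length {len(trace.angle)}"
        )
    smoothed = (
        pd.Series(trace.angle)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return TailTrace(
        angle=smoothed,
        fps=trace.fps,
        stim_frame=trace.stim_frame,
        head_xy=trace.head_xy,
        larva_id=trace.larva_id,
        trial_id=trace.trial_id,
    )


def _find_start(
    abs_diff: np.ndarray,
    from_frame: int,
    to_frame: int | None,
    thresh: float,
    n_confirm: int,
) -> int | None:
    """First frame in [from_frame, to_frame) whose differential and the next
    ``n_confirm`` differentials all exceed ``thresh``."""
    hi = len(abs_diff) if to_frame is None else min(to_frame, len(abs_diff))
    above = abs_diff > thresh
    for f in range(from_frame, hi - n_confirm):
        if above[f : f + n_confirm + 1].all():
            return f
    return None


def detect_bout(
    trace: TailTrace,
    start_diff_thresh: float = START_DIFF_THRESH,
    n_confirm: int = N_CONFIRM,
    quiet_thresh: float = QUIET_THRESH,
    quiet_len: int = QUIET_LEN,
) -> BoutEvent | None:
    """Detect the movement bout following the stimulus.

    The start is the first post-stimulus frame at which the absolute
    frame-to-frame angle differential exceeds ``start_diff_thresh`` and
    stays above it for the next ``n_confirm`` frames.  The end is the last
    frame of the first run of ``quiet_len`` consecutive frames after the
    start whose differentials all stay below ``quiet_thresh``.  Returns
    ``None`` if no start is found; if the trace ends before a quiet run
    completes the bout is truncated at the trace end and flagged.
    """
    if min(start_diff_thresh, quiet_thresh) <= 0:
        raise ValueError("thresholds must be positive")
    abs_diff = np.abs(np.diff(trace.angle))
    start = _find_start(abs_diff, trace.stim_frame, None, start_diff_thresh, n_confirm)
    if start is None:
        return None

    quiet = abs_diff < quiet_thresh
    run = 0
    for f in range(start + 1, len(quiet)):
        run = run + 1 if quiet[f] else 0
        if run == quiet_len:
            # diff index f covers frames f..f+1 -> last quiet frame is f + 1
            return BoutEvent(start_frame=start, end_frame=f + 1)
    return BoutEvent(
        start_frame=start, end_frame=len(trace.angle) - 1, truncated=True
    )


def detect_peaks(
    trace: TailTrace,
    bout: BoutEvent,
    min_sep_ms: float = 2.0,
    min_rise_deg: float = 1.0,
    lookback_ms: float = 5.0,
) -> list[tuple[int, float]]:
    """Accepted alternating tail-angle extrema within a bout.

    Candidate extrema are local maxima and minima of the angle (plateaus
    contribute their first frame).  A candidate at frame ``t`` is accepted
    only if |angle(t)| exceeds |angle(t - lookback)| by at least
    ``min_rise_deg`` and it lies at least ``min_sep_ms`` after the
    previously accepted peak; when two candidates violate the separation
    the earlier one is kept.  A candidate of the same extremum type as the
    last accepted peak replaces it when larger in magnitude.
    """
    theta = trace.angle
    lo, hi = bout.start_frame, bout.end_frame
    if hi - lo < 2:
        return []
    min_sep = min_sep_ms * trace.fps / 1000.0
    lookback = max(1, int(round(lookback_ms * trace.fps / 1000.0)))

    # run-compress equal consecutive samples so plateau extrema are found
    # once, at the first frame of the plateau
    change = np.flatnonzero(np.diff(theta) != 0) + 1
    run_starts = np.concatenate(([0], change))
    run_vals = theta[run_starts]
    candidates: list[tuple[int, int]] = []  # (frame, +1 max / -1 min)
    for j in range(1, len(run_vals) - 1):
        t = int(run_starts[j])
        t_end = int(run_starts[j + 1]) - 1  # last frame of the plateau
        if t_end < lo or t > hi:
            continue
        left = run_vals[j] - run_vals[j - 1]
        right = run_vals[j + 1] - run_vals[j]
        if left > 0 and right < 0:
            candidates.append((t, 1))
        elif left < 0 and right > 0:
            candidates.append((t, -1))

    accepted: list[tuple[int, float]] = []
    last_kind = 0
    for t, kind in candidates:
        ref = theta[max(0, t - lookback)]
        if abs(theta[t]) < abs(ref) + min_rise_deg:
            continue
        if accepted and t - accepted[-1][0] < min_sep:
            continue  # separation violation: keep the earlier peak
        if accepted and kind == last_kind:
            # alternation break: keep whichever extremum is larger
            if abs(theta[t]) > abs(accepted[-1][1]):
                accepted[-1] = (t, theta[t])
            continue
        accepted.append((t, theta[t]))
        last_kind = kind
    return accepted


def classify_maneuver(
    bout: BoutEvent,
    peaks: list[tuple[int, float]] | None = None,
    asym_ratio: float = 1.5,
    slow_amp_max: float = 25.0,
) -> str:
    """Categorize a bout as ``escape``, ``slow_swim`` or ``unclassified``.

    Escapes start with an asymmetrical C-bend — the first peak at least
    ``asym_ratio`` times the magnitude of the return bend — and complete at
    least one full cycle.  Slow swims are symmetric (first bend below that
    ratio), all peaks under ``slow_amp_max`` degrees, and complete more
    than one cycle.  Cycles are half the peak count.
    """
    if peaks is None:
        peaks = bout.peaks
    amps = np.abs([a for _, a in peaks])
    cycles = len(amps) / 2.0
    if len(amps) < 2:
        return "unclassified"
    asymmetric = amps[1] == 0 or amps[0] >= asym_ratio * amps[1]
    if asymmetric and cycles >= 1:
        return "escape"
    if not asymmetric and cycles > 1 and np.all(amps < slow_amp_max):
        return "slow_swim"
    return "unclassified"


def kinematic_summary(
    trace: TailTrace,
    bout: BoutEvent,
    peaks: list[tuple[int, float]] | None = None,
    category: str | None = None,
) -> KinematicSummary:
    """Derive per-trial kinematic variables from a bout and its peaks.

    ``mean_tbf_hz`` is the mean over hemi-periods of ``fps / (2 h)`` and is
    ``None`` with fewer than two peaks.  ``distance_mm`` is the cumulative
    head path length over the bout frames when head positions are present,
    and ``speed_mm_s`` is distance over duration.
    """
    if peaks is None:
        peaks = bout.peaks
    duration_ms = (bout.end_frame - bout.start_frame) / trace.fps * 1000.0
    frames = np.array([f for f, _ in peaks], dtype=int)
    n_osc = len(frames) / 2.0

    mean_tbf = None
    if len(frames) >= 2:
        hemi = np.diff(frames)
        mean_tbf = float(np.mean(trace.fps / (2.0 * hemi)))

    first_amp = float(peaks[0][1]) if peaks else None
    first_lat = int(frames[0] - trace.stim_frame) if peaks else None

    distance = speed = None
    if trace.head_xy is not None:
        seg = trace.head_xy[bout.start_frame : bout.end_frame + 1]
        distance = float(np.sum(np.hypot(*np.diff(seg, axis=0).T)))
        speed = distance / (duration_ms / 1000.0)

    if category is None:
        category = classify_maneuver(bout, peaks)
    return KinematicSummary(
        duration_ms=duration_ms,
        n_oscillations=n_osc,
        mean_tbf_hz=mean_tbf,
        category=category,
        first_peak_amplitude_deg=first_amp,
        first_peak_latency_frames=first_lat,
        distance_mm=distance,
        speed_mm_s=speed,
    )


def exclude_trial(
    trace: TailTrace,
    peaks: list[tuple[int, float]],
    max_latency_frames: int = 20,
    min_first_peak_deg: float = 60.0,
    start_diff_thresh: float = START_DIFF_THRESH,
    n_confirm: int = N_CONFIRM,
) -> tuple[bool, str | None]:
    """Apply the escape-assay trial-exclusion criteria.

    A trial is excluded when (i) suprathreshold movement is detected before
    the stimulus, (ii) the first post-stimulus peak comes more than
    ``max_latency_frames`` after the stimulus, or (iii) the first peak is
    below ``min_first_peak_deg`` — bouts without an initial C-bend are not
    escapes.  Returns ``(kept, reason)``.
    """
    abs_diff = np.abs(np.diff(trace.angle))
    pre = _find_start(abs_diff, 0, trace.stim_frame, start_diff_thresh, n_confirm)
    if pre is not None and pre + n_confirm < trace.stim_frame:
        return False, "pre_stim_movement"
    post = [(f, a) for f, a in peaks if f >= trace.stim_frame]
    if not post or post[0][0] - trace.stim_frame > max_latency_frames:
        return False, "late_first_peak"
    if abs(post[0][1]) < min_first_peak_deg:
        return False, "weak_first_peak"
    return True, None


def hemi_period_cutoff_frames(fps: float, cutoff_hz: float = 30.0) -> float:
    """Hemi-period (frames) equivalent to a cycle-frequency cutoff.

    One hemi-period is half a cycle, so ``fps / (2 * cutoff_hz)``; at
    650 fps and 30 Hz this is 650/60 frames.
    """
    return fps / (2.0 * cutoff_hz)


def split_fast_slow(
    hemi_periods: np.ndarray | list[float],
    fps: float,
    cutoff_hz: float = 30.0,
    peak_frames: np.ndarray | None = None,
    head_xy: np.ndarray | None = None,
) -> CycleComponent:
    """Label each hemi-period fast or slow and summarize each component.

    Hemi-periods shorter than the cutoff (``fps / (2 * cutoff_hz)`` frames)
    are fast; others are slow.  The decomposition enforces a single
    fast-to-slow transition: once a slow hemi-period has occurred, later
    sub-cutoff hemi-periods are labeled ``excluded`` rather than fast.

    When ``peak_frames`` (one more entry than hemi-periods) and ``head_xy``
    are given, each component summary additionally carries the head path
    length over its hemi-periods and the resulting speed.
    """
    hemi = np.asarray(hemi_periods, dtype=float)
    cutoff = hemi_period_cutoff_frames(fps, cutoff_hz)
    labels: list[str] = []
    seen_slow = False
    for h in hemi:
        if h >= cutoff:
            labels.append("slow")
            seen_slow = True
        elif seen_slow:
            labels.append("excluded")
        else:
            labels.append("fast")

    summaries: dict[str, dict[str, float | None]] = {}
    for lab in ("fast", "slow", "excluded"):
        idx = [i for i, l in enumerate(labels) if l == lab]
        sel = hemi[idx]
        summ: dict[str, float | None] = {
            "n_hemi_periods": float(len(sel)),
            "n_oscillations": len(sel) / 2.0,
            "duration_ms": float(np.sum(sel)) / fps * 1000.0,
            "mean_tbf_hz": float(np.mean(fps / (2.0 * sel))) if len(sel) else None,
        }
        if peak_frames is not None and head_xy is not None and len(sel):
            dist = 0.0
            for i in idx:
                a, b = int(peak_frames[i]), int(peak_frames[i + 1])
                seg = head_xy[a : b + 1]
                dist += float(np.sum(np.hypot(*np.diff(seg, axis=0).T)))
            summ["distance_mm"] = dist
            summ["speed_mm_s"] = (
                dist / (summ["duration_ms"] / 1000.0) if summ["duration_ms"] else None
            )
        summaries[lab] = summ
    return CycleComponent(hemi_periods=hemi, labels=labels, summaries=summaries)
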