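"""Calcium-imaging recruitment analysis and ventral-nerve-root QC.

Spinal motor neurons expressing GCaMP6f are imaged at 20 Hz in paralyzed
larvae while fictive behaviors (spontaneous slow swims, induced escapes)
are monitored on a ventral nerve root (VNR) electrode.  For each ROI we
compute ΔF/F, decide per behavioral event whether the cell was active —
using the maximum ΔF/F of out-of-focus background ROIs during the event as
the activity threshold — normalize dorso-ventral soma positions to the
spinal-cord limits, and summarize recruitment per behavior.  VNR traces
are burst-detected and quality-controlled on baseline noise and SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellRecord",
    "BehaviorEvent",
    "VnrRecording",
    "compute_dff",
    "classify_active",
    "normalize_dv",
    "recruitment_summary",
    "detect_vnr_bursts",
]

F0_WINDOW_FRAMES = 20  # 1 s at 20 Hz
FAST_BURST_HZ = 30.0


@dataclass
class CellRecord:
    """One ROI's fluorescence trace and dorso-ventral position."""

    roi_id: str
    fluorescence: np.ndarray  # arbitrary units, 20 Hz frames
    dv_raw: float
    dv_norm: float | None = None
    events: dict[str, dict] = field(default_factory=dict)  # event_id -> result


@dataclass
class BehaviorEvent:
    """A fictive behavioral event aligned to imaging frames."""

    event_id: str
    kind: str  # "swim" | "escape"
    onset_frame: int
    offset_frame: int

    def __post_init__(self) -> None:
        if self.onset_frame >= self.offset_frame:
            raise ValueError("event onset must precede offset")
        if self.kind not in ("swim", "escape"):
            raise ValueError(f"unknown behavior kind {self.kind!r}")


@dataclass
class VnrBurst:
    onset_s: float
    offset_s: float
    amplitude_mv: float  # peak-to-peak


@dataclass
class VnrRecording:
    """Extracellular ventral-nerve-root trace (mV, 10 kHz)."""

    voltage_mv: np.ndarray
    fs_hz: float = 10_000.0


def compute_dff(
    fluorescence: np.ndarray, baseline_window: slice | tuple[int, int]
) -> np.ndarray:
    """Percent ΔF/F relative to the mean over ``baseline_window``.

    ΔF/F(t) = 100 (F(t) - F0) / F0 with F0 the baseline-window mean; the
    result is invariant to positive rescaling of F.
    """
    f = np.asarray(fluorescence, dtype=float)
    if isinstance(baseline_window, tuple):
        baseline_window = slice(*baseline_window)
    f0 = float(np.mean(f[baseline_window]))
    if f0 <= 0:
        raise ValueError(f"baseline fluorescence must be positive, got {f0}")
    return 100.0 * (f - f0) / f0


def _event_baseline(event: BehaviorEvent, n_frames: int) -> slice:
    lo = max(0, event.onset_frame - F0_WINDOW_FRAMES)
    hi = max(lo + 1, event.onset_frame)
    return slice(lo, hi)


def classify_active(
    cells: list[CellRecord],
    background_ventral: np.ndarray,
    background_dorsal: np.ndarray,
    event: BehaviorEvent,
) -> dict[str, bool]:
    """Call each cell active or silent for one behavioral event.

    The activity threshold is the maximum ΔF/F reached during the event by
    the out-of-focus background ROIs: the ventral background for swims,
    the larger of ventral and dorsal backgrounds for escapes (matching
    where out-of-focus light arises in each behavior).  A cell is active
    iff its peak ΔF/F within the event window strictly exceeds the
    threshold.  Results are also stored on each cell's ``events`` map.
    """
    bg_v = np.asarray(background_ventral, dtype=float)
    bg_d = np.asarray(background_dorsal, dtype=float)
    if len(bg_v) < event.offset_frame or len(bg_d) < event.offset_frame:
        raise ValueError("background traces do not cover the event window")
    base = _event_baseline(event, len(bg_v))
    win = slice(event.onset_frame, event.offset_frame + 1)

    thr_v = float(np.max(compute_dff(bg_v, base)[win]))
    thr_d = float(np.max(compute_dff(bg_d, base)[win]))
    threshold = thr_v if event.kind == "swim" else max(thr_v, thr_d)

    flags: dict[str, bool] = {}
    for cell in cells:
        dff = compute_dff(cell.fluorescence, base)
        peak = float(np.max(dff[win]))
        active = peak > threshold
        flags[cell.roi_id] = active
        cell.events[event.event_id] = {
            "kind": event.kind,
            "peak_dff": peak,
            "active": active,
            "threshold": threshold,
        }
    return flags


def normalize_dv(
    dv_raw: float | np.ndarray, ventral_limit: float, dorsal_limit: float
) -> np.ndarray:
    """Normalize dorso-ventral positions to 0 (ventral limit) .. 1 (dorsal).

    Out-of-band inputs are clipped to [0, 1].
    """
    if ventral_limit == dorsal_limit:
        raise ValueError("ventral and dorsal limits must differ")
    x = (np.asarray(dv_raw, dtype=float) - ventral_limit) / (
        dorsal_limit - ventral_limit
    )
    return np.clip(x, 0.0, 1.0)


def recruitment_summary(
    cells: list[CellRecord], events: list[BehaviorEvent]
) -> dict[str, dict[str, float | None]]:
    """Per-behavior recruitment statistics.

    A cell counts as active for a behavior if it was active in any event
    of that kind.  Reports the proportion of active cells (percent), the
    mean peak ΔF/F across active cells, and their mean normalized
    dorso-ventral position.
    """
    out: dict[str, dict[str, float | None]] = {}
    kinds = sorted({e.kind for e in events})
    for kind in kinds:
        ids = [e.event_id for e in events if e.kind == kind]
        active_cells = []
        peaks = []
        for cell in cells:
            recs = [cell.events[i] for i in ids if i in cell.events]
            if not recs:
                continue
            if any(r["active"] for r in recs):
                active_cells.append(cell)
                peaks.append(max(r["peak_dff"] for r in recs if r["active"]))
        n_total = len(cells)
        n_active = len(active_cells)
        dvs = [c.dv_norm for c in active_cells if c.dv_norm is not None]
        out[kind] = {
            "n_active": float(n_active),
            "n_total": float(n_total),
            "proportion_active_pct": 100.0 * n_active / n_total if n_total else None,
            "mean_peak_dff": float(np.mean(peaks)) if peaks else None,
            "mean_dv_norm": float(np.mean(dvs)) if dvs else None,
        }
    return out


def detect_vnr_bursts(
    vnr: VnrRecording,
    noise_max_mv: float = 0.05,
    snr_min: float = 3.0,
    envelope_ms: float = 2.0,
    min_sep_ms: float = 5.0,
) -> dict:
    """Detect fictive locomotor bursts and apply recording QC.

    The detector rectifies the median-subtracted trace, smooths it with a
    short moving average, and takes contiguous regions where the envelope
    exceeds 3x the robust (MAD-derived) baseline SD; regions closer than
    ``min_sep_ms`` are merged.  Baseline noise amplitude is taken as twice
    the robust SD.  QC fails when that amplitude exceeds ``noise_max_mv``
    or, if bursts are present, when the envelope SNR is at or below
    ``snr_min``.  Instantaneous burst frequency is the reciprocal of the
    inter-onset interval; a bout with any frequency above 30 Hz is called
    escape-like, otherwise swim-like.
    """
    v = np.asarray(vnr.voltage_mv, dtype=float)
    fs = vnr.fs_hz
    centered = v - np.median(v)
    rect = np.abs(centered)
    win = max(1, int(round(envelope_ms * fs / 1000.0)))
    kernel = np.ones(win) / win
    env = np.convolve(rect, kernel, mode="same")

    mad = float(np.median(np.abs(centered - np.median(centered))))
    noise_sd = mad * 1.4826
    noise_amplitude = 2.0 * noise_sd

    bursts: list[VnrBurst] = []
    snr = None
    if noise_sd > 0:
        above = env > 3.0 * noise_sd
        idx = np.flatnonzero(above)
        if idx.size:
            gaps = np.flatnonzero(np.diff(idx) > 1)
            seg_starts = np.concatenate(([idx[0]], idx[gaps + 1]))
            seg_ends = np.concatenate((idx[gaps], [idx[-1]]))
            # merge segments separated by < min_sep_ms
            min_gap = int(round(min_sep_ms * fs / 1000.0))
            merged = [[int(seg_starts[0]), int(seg_ends[0])]]
            for s, e in zip(seg_starts[1:], seg_ends[1:]):
                if s - merged[-1][1] < min_gap:
                    merged[-1][1] = int(e)
                else:
                    merged.append([int(s), int(e)])
            for s, e in merged:
                seg = v[s : e + 1]
                bursts.append(
                    VnrBurst(
                        onset_s=s / fs,
                        offset_s=e / fs,
                        amplitude_mv=float(seg.max() - seg.min()),
                    )
                )
            snr = float(env.max() / noise_sd)

    onsets = np.array([b.onset_s for b in bursts])
    freqs = 1.0 / np.diff(onsets) if len(onsets) >= 2 else np.array([])

    qc_pass = noise_amplitude <= noise_max_mv and (snr is None or snr > snr_min)
    kind = None
    if len(freqs):
        kind = "escape_like" if np.any(freqs > FAST_BURST_HZ) else "swim_like"
    return {
        "bursts": bursts,
        "burst_frequencies_hz": freqs,
        "noise_amplitude_mv": noise_amplitude,
        "snr": snr,
        "qc_pass": bool(qc_pass),
        "event_type": kind,
    }
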