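"""Quantification of GFP-Aequorin bioluminescence photon trains.

A photomultiplier tube counts photons emitted by the calcium-bound
aequorin reporter at 1 ms resolution while the larva responds to an
acoustic stimulus.  The processing chain is: bin the counts to 10 ms,
smooth with a centered running average, estimate the dark/baseline photon
rate from a linear fit of the cumulative pre-stimulus count, subtract it,
then detect the signal with three-point differential rules and
characterize it (amplitude in photons/10 ms, time-to-peak, exponential
decay coefficient gated on fit quality, SNR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PhotonTrace",
    "BioluminescenceSignal",
    "bin_photons",
    "smooth_signal",
    "estimate_baseline",
    "detect_signal",
    "fit_decay",
    "normalize_per_larva",
    "process_trace",
]

R2_GATE = 0.95


@dataclass
class PhotonTrace:
    """Raw 1 ms photon counts for one trial."""

    counts_1ms: np.ndarray
    stim_time_ms: int
    larva_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts_1ms)
        if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
            raise ValueError("photon counts must be non-negative integers")
        self.counts_1ms = counts.astype(int)
        if not (0 <= self.stim_time_ms < len(self.counts_1ms)):
            raise ValueError("stim_time_ms outside trace")


@dataclass
class BioluminescenceSignal:
    """Detected, baseline-subtracted bioluminescence signal (10 ms bins)."""

    start_ms: float
    peak_ms: float
    end_ms: float
    amplitude: float  # photons/10 ms, baseline-subtracted
    time_to_peak_ms: float
    snr: float | None = None
    decay_coef: float | None = None  # 1/ms; only reported when decay_r2 > gate
    decay_r2: float | None = None
    end_truncated: bool = False
    normalized_amplitude: float | None = None


def bin_photons(counts_1ms: np.ndarray, bin_ms: int = 10) -> np.ndarray:
    """Sum 1 ms counts into consecutive ``bin_ms`` bins.

    A trailing partial bin is dropped; total counts over the binned span
    are conserved.
    """
    counts = np.asarray(counts_1ms)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("photon counts must be integers")
    n_bins = len(counts) // bin_ms
    return counts[: n_bins * bin_ms].reshape(n_bins, bin_ms).sum(axis=1)


def smooth_signal(binned: np.ndarray, window: int = 10) -> np.ndarray:
    """Centered running average; edge bins use shrunken windows."""
    binned = np.asarray(binned, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(binned):
        raise ValueError(f"window {window} exceeds trace length {len(binned)}")
    return (
        pd.Series(binned)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def estimate_baseline(trace: PhotonTrace) -> float:
    """Baseline photon rate in photons/10 ms from the pre-stimulus window.

    The rate is the least-squares slope of the cumulative photon count
    versus time (ms) before the stimulus, rescaled to photons per 10 ms.
    """
    if trace.stim_time_ms < 100:
        raise ValueError("need >= 100 ms of pre-stimulus data")
    pre = trace.counts_1ms[: trace.stim_time_ms]
    if not pre.any():
        return 0.0
    cum = np.cumsum(pre).astype(float)
    t = np.arange(len(pre), dtype=float)
    slope = np.polyfit(t, cum, 1)[0]  # photons/ms
    return float(max(slope, 0.0) * 10.0)


def process_trace(
    trace: PhotonTrace,
    bin_ms: int = 10,
    smooth_window: int = 10,
) -> tuple[np.ndarray, float, int]:
    """Bin, smooth, and baseline-subtract a photon trace.

    Returns ``(processed, baseline_rate, stim_bin)`` where ``processed`` is
    the smoothed binned trace minus the uniform baseline rate, floored at
    zero.
    """
    binned = bin_photons(trace.counts_1ms, bin_ms)
    smoothed = smooth_signal(binned, smooth_window)
    rate = estimate_baseline(trace) * (bin_ms / 10.0)
    processed = np.maximum(smoothed - rate, 0.0)
    return processed, rate, trace.stim_time_ms // bin_ms


def detect_signal(
    processed: np.ndarray,
    stim_bin: int,
    bin_ms: int = 10,
    start_diff: float = 0.4,
    end_diff: float = 0.2,
) -> BioluminescenceSignal | None:
    """Detect a bioluminescence signal in a processed (binned, smoothed,
    baseline-subtracted) trace.

    The start is the first post-stimulus point whose next three
    differentials all exceed ``start_diff`` photons/10 ms; the end is the
    first point after the peak whose next three differentials are all
    below ``end_diff`` in magnitude.  Amplitude is the trace value at the
    peak; SNR is the amplitude over the pre-stimulus SD of the processed
    trace.  Returns ``None`` if no start is found.
    """
    d = np.diff(processed)
    start = None
    for i in range(stim_bin, len(d) - 2):
        if d[i] > start_diff and d[i + 1] > start_diff and d[i + 2] > start_diff:
            start = i
            break
    if start is None:
        return None

    peak = start + int(np.argmax(processed[start:]))
    end = None
    for i in range(peak, len(d) - 2):
        if (
            abs(d[i]) < end_diff
            and abs(d[i + 1]) < end_diff
            and abs(d[i + 2]) < end_diff
        ):
            end = i
            break
    truncated = end is None
    if end is None:
        end = len(processed) - 1
    peak = start + int(np.argmax(processed[start : end + 1]))

    pre = processed[:stim_bin]
    sd = float(np.std(pre)) if len(pre) else 0.0
    amplitude = float(processed[peak])
    return BioluminescenceSignal(
        start_ms=start * bin_ms,
        peak_ms=peak * bin_ms,
        end_ms=end * bin_ms,
        amplitude=amplitude,
        time_to_peak_ms=(peak - start) * bin_ms,
        snr=amplitude / sd if sd > 0 else None,
        end_truncated=truncated,
    )


def fit_decay(
    processed: np.ndarray,
    peak_bin: int,
    end_bin: int,
    bin_ms: int = 10,
    r2_gate: float = R2_GATE,
) -> tuple[float | None, float]:
    """One-term exponential fit ``A exp(-k t)`` between peak and end.

    Returns ``(decay_coef, r2)`` with the coefficient in 1/ms.  The
    coefficient is ``None`` when the fit's R-squared does not exceed
    ``r2_gate`` or the fit fails.
    """
    if end_bin - peak_bin < 5:
        raise ValueError("need >= 5 bins between peak and end")
    y = np.asarray(processed[peak_bin : end_bin + 1], dtype=float)
    t = np.arange(len(y), dtype=float) * bin_ms
    if np.all(y <= 0):
        return None, 0.0

    # log-linear initialisation on the positive samples
    pos = y > 0
    b0, a0 = np.polyfit(t[pos], np.log(y[pos]), 1)
    p0 = (float(np.exp(a0)), float(max(-b0, 1e-6)))
    try:
        popt, _ = curve_fit(
            lambda tt, a, k: a * np.exp(-k * tt), t, y, p0=p0, maxfev=5000
        )
    except RuntimeError:
        return None, 0.0
    fit = popt[0] * np.exp(-popt[1] * t)
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    k = float(popt[1])
    return (k if r2 > r2_gate else None), r2


def normalize_per_larva(amplitudes: pd.DataFrame) -> pd.Series:
    """Normalize trial amplitudes within each larva by its maximum.

    ``amplitudes`` needs columns ``larva_id`` and ``amplitude``.  Larvae
    whose maximum amplitude is zero get zeros (degenerate, flaggable by
    the caller).  Values lie in [0, 1].
    """
    def _norm(g: pd.Series) -> pd.Series:
        m = g.max()
        return g / m if m > 0 else g * 0.0

    return amplitudes.groupby("larva_id")["amplitude"].transform(_norm)
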