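"""Optogenetic connectivity analysis of Rohon-Beard to V2a synapses.

Whole-cell recordings at 10 kHz are aligned to brief (1-5 ms) blue-light
pulses that drive CoChR-expressing Rohon-Beard (RB) mechanosensory
neurons.  Current-clamp sweeps from RB cells yield the spike time-to-peak
after light onset; voltage-clamp sweeps from target V2a interneurons yield
EPSC onset latency and amplitude.  The lag between mean spike time-to-peak
and mean EPSC onset, compared against a 3 ms cutoff, classifies the
connection as monosynaptic; subtracting a fixed synaptic delay converts
the residual lag and an axonal distance into a conduction velocity, and
Ohm's law converts EPSC amplitude and input resistance into an estimated
depolarization.  Current-step protocols provide input resistance and
rheobase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConnectivitySweep",
    "ConnectionStats",
    "StepProtocol",
    "detect_spike_ttp",
    "detect_epsc",
    "compute_lag",
    "classify_monosynaptic",
    "conduction_velocity",
    "estimate_depolarization",
    "fit_step_protocol",
    "summarize_connection",
]

SPIKE_THRESHOLD_MV = 0.0
MONOSYNAPTIC_CUTOFF_MS = 3.0
SYNAPTIC_DELAY_MS = 0.5
SEARCH_WINDOW_MS = 20.0
BASELINE_MS = 50.0


@dataclass
class ConnectivitySweep:
    """One light-aligned sweep (mV in current clamp, pA in voltage clamp)."""

    trace: np.ndarray
    fs_hz: float
    pulse_onsets_ms: list[float]
    pulse_duration_ms: float
    mode: str  # "cc" | "vc"
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.mode not in ("cc", "vc"):
            raise ValueError(f"mode must be 'cc' or 'vc', got {self.mode!r}")
        if self.pulse_duration_ms <= 0:
            raise ValueError("pulse duration must be positive")
        if any(
            b <= a for a, b in zip(self.pulse_onsets_ms, self.pulse_onsets_ms[1:])
        ):
            raise ValueError("pulse onsets must be increasing")


@dataclass
class ConnectionStats:
    """Per-connection summary across stimulations."""

    spike_ttp_ms: float
    spike_ttp_se: float
    epsc_onset_ms: float
    epsc_onset_se: float
    lag_ms: float
    monosynaptic: bool
    epsc_amp_pa: float | None = None
    est_depol_mv: float | None = None
    conduction_velocity_m_s: float | None = None
    n_spikes: int = 0
    n_epscs: int = 0


@dataclass
class StepProtocol:
    """Square current-step protocol (250 ms steps) for passive properties."""

    currents_pa: list[float]
    traces_mv: list[np.ndarray]
    fs_hz: float
    step_start_ms: float
    step_duration_ms: float = 250.0


def _ms_to_idx(ms: float, fs_hz: float) -> int:
    return int(round(ms * fs_hz / 1000.0))


def detect_spike_ttp(
    sweep: ConnectivitySweep,
    pulse_onset_ms: float,
    threshold_mv: float = SPIKE_THRESHOLD_MV,
    window_ms: float = SEARCH_WINDOW_MS,
) -> float | None:
    """Spike time-to-peak (ms) after one light pulse, or ``None``.

    A spike is a suprathreshold excursion crossing ``threshold_mv`` within
    ``window_ms`` of the pulse onset; the time-to-peak is measured to the
    maximum of the first such excursion.
    """
    if sweep.mode != "cc":
        raise ValueError("spike detection requires a current-clamp sweep")
    lo = _ms_to_idx(pulse_onset_ms, sweep.fs_hz)
    hi = min(len(sweep.trace), _ms_to_idx(pulse_onset_ms + window_ms, sweep.fs_hz))
    seg = sweep.trace[lo:hi]
    above = seg >= threshold_mv
    if not above.any():
        return None
    first = int(np.argmax(above))
    stop = first
    while stop < len(seg) and above[stop]:
        stop += 1
    peak = first + int(np.argmax(seg[first:stop]))
    return peak / sweep.fs_hz * 1000.0


def detect_epsc(
    sweep: ConnectivitySweep,
    pulse_onset_ms: float,
    k_sd: float = 3.0,
    n_confirm: int = 5,
    baseline_ms: float = BASELINE_MS,
    window_ms: float = SEARCH_WINDOW_MS,
) -> tuple[float, float] | None:
    """EPSC onset latency (ms after pulse onset) and amplitude (pA).

    The onset is the first sample after the pulse where the inward
    (negative-going) deflection from the pre-pulse baseline mean exceeds
    ``k_sd`` baseline SDs for ``n_confirm`` consecutive samples; the
    amplitude is the largest inward deflection within ``window_ms`` of the
    onset.  Returns ``None`` when no qualifying deflection exists.
    """
    if sweep.mode != "vc":
        raise ValueError("EPSC detection requires a voltage-clamp sweep")
    onset_idx = _ms_to_idx(pulse_onset_ms, sweep.fs_hz)
    b_lo = max(0, onset_idx - _ms_to_idx(baseline_ms, sweep.fs_hz))
    baseline = sweep.trace[b_lo:onset_idx]
    if len(baseline) < 2:
        raise ValueError("insufficient pre-pulse baseline")
    mu, sd = float(np.mean(baseline)), float(np.std(baseline))
    if sd == 0:
        sd = 1e-12

    deflection = mu - sweep.trace  # inward currents are negative
    above = deflection > k_sd * sd
    hi = min(len(above), onset_idx + _ms_to_idx(window_ms, sweep.fs_hz))
    onset = None
    for i in range(onset_idx, hi - n_confirm + 1):
        if above[i : i + n_confirm].all():
            onset = i
            break
    if onset is None:
        return None
    amp_hi = min(len(deflection), onset + _ms_to_idx(window_ms, sweep.fs_hz))
    amplitude = float(np.max(deflection[onset:amp_hi]))
    return (onset - onset_idx) / sweep.fs_hz * 1000.0, amplitude


def compute_lag(
    spike_ttps_ms: list[float] | np.ndarray, epsc_onsets_ms: list[float] | np.ndarray
) -> float:
    """Mean EPSC onset minus mean spike time-to-peak, in ms."""
    spikes = np.asarray(spike_ttps_ms, dtype=float)
    epscs = np.asarray(epsc_onsets_ms, dtype=float)
    if spikes.size == 0 or epscs.size == 0:
        raise ValueError("both latency sets must be non-empty")
    return float(np.mean(epscs) - np.mean(spikes))


def classify_monosynaptic(lag_ms: float, cutoff_ms: float = MONOSYNAPTIC_CUTOFF_MS) -> bool:
    """True iff the spike-to-EPSC lag is strictly below the cutoff."""
    if not np.isfinite(lag_ms):
        raise ValueError("lag must be finite")
    return lag_ms < cutoff_ms


def conduction_velocity(
    lag_ms: float,
    axon_distance_mm: float,
    synaptic_delay_ms: float = SYNAPTIC_DELAY_MS,
) -> float:
    """Axonal conduction velocity (m/s) from lag minus synaptic delay.

    v = distance / (lag - delay); mm/ms equals m/s.
    """
    if axon_distance_mm <= 0:
        raise ValueError("axon distance must be positive")
    if lag_ms <= synaptic_delay_ms:
        raise ValueError("lag must exceed the synaptic delay")
    return axon_distance_mm / (lag_ms - synaptic_delay_ms)


def estimate_depolarization(epsc_amp_pa: float, input_resistance_mohm: float) -> float:
    """Estimated somatic depolarization (mV) from EPSC amplitude and Rin.

    ΔV = I R; pA times MΩ gives µV, reported in mV.
    """
    if epsc_amp_pa <= 0 or input_resistance_mohm <= 0:
        raise ValueError("amplitude and resistance must be positive")
    return epsc_amp_pa * input_resistance_mohm * 1e-3


def _count_spikes(trace: np.ndarray, threshold_mv: float = SPIKE_THRESHOLD_MV) -> int:
    above = trace >= threshold_mv
    return int(np.sum(np.diff(above.astype(int)) == 1) + (1 if above[0] else 0))


def fit_step_protocol(protocol: StepProtocol) -> tuple[float | None, float | None]:
    """Input resistance (MΩ) and rheobase (pA) from a current-step protocol.

    The steady-state voltage deflection of each subthreshold step (mean
    over the last half of the step, minus the pre-step baseline) is
    regressed against injected current; the slope in mV/pA converts to MΩ
    (x1000).  Rheobase is the smallest current eliciting at least one
    spike, ``None`` if none does; input resistance is ``None`` (flagged)
    when fewer than two subthreshold steps exist.
    """
    fs = protocol.fs_hz
    s0 = _ms_to_idx(protocol.step_start_ms, fs)
    s1 = _ms_to_idx(protocol.step_start_ms + protocol.step_duration_ms, fs)
    mid = (s0 + s1) // 2

    dvs, dis, spiking = [], [], []
    for i_pa, trace in zip(protocol.currents_pa, protocol.traces_mv):
        trace = np.asarray(trace, dtype=float)
        base = float(np.mean(trace[:s0]))
        n_spikes = _count_spikes(trace[s0:s1])
        spiking.append(n_spikes > 0)
        if n_spikes == 0:
            dvs.append(float(np.mean(trace[mid:s1])) - base)
            dis.append(i_pa)

    rin = None
    if len(dis) >= 2:
        slope = np.polyfit(dis, dvs, 1)[0]  # mV/pA = GΩ
        rin = float(slope * 1000.0)
    rheobase = None
    supra = [i for i, s in zip(protocol.currents_pa, spiking) if s]
    if supra:
        rheobase = float(min(supra))
    return rin, rheobase


def summarize_connection(
    spike_ttps_ms: list[float],
    epsc_results: list[tuple[float, float]],
    cutoff_ms: float = MONOSYNAPTIC_CUTOFF_MS,
    synaptic_delay_ms: float = SYNAPTIC_DELAY_MS,
    axon_distance_mm: float | None = None,
    input_resistance_mohm: float | None = None,
) -> ConnectionStats:
    """Aggregate per-stimulation detections into connection statistics."""
    spikes = np.asarray(spike_ttps_ms, dtype=float)
    onsets = np.asarray([o for o, _ in epsc_results], dtype=float)
    amps = np.asarray([a for _, a in epsc_results], dtype=float)
    lag = compute_lag(spikes, onsets)
    mono = classify_monosynaptic(lag, cutoff_ms)

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    cv = None
    if axon_distance_mm is not None and lag > synaptic_delay_ms:
        cv = conduction_velocity(lag, axon_distance_mm, synaptic_delay_ms)
    depol = None
    mean_amp = float(np.mean(amps)) if len(amps) else None
    if input_resistance_mohm is not None and mean_amp:
        depol = estimate_depolarization(mean_amp, input_resistance_mohm)
    return ConnectionStats(
        spike_ttp_ms=float(np.mean(spikes)),
        spike_ttp_se=se(spikes),
        epsc_onset_ms=float(np.mean(onsets)),
        epsc_onset_se=se(onsets),
        lag_ms=lag,
        monosynaptic=mono,
        epsc_amp_pa=mean_amp,
        est_depol_mv=depol,
        conduction_velocity_m_s=cv,
        n_spikes=len(spikes),
        n_epscs=len(onsets),
    )
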