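"""Seeded synthetic-data generators for every recording modality.

Each generator emulates one of the study's input modalities with fully
known ground truth, so every analysis stage can be exercised end to end
without any recording on disk:

* tail-angle traces (escape: large initial C-bend, amplitude and
  instantaneous frequency decaying together across the 30 Hz fast/slow
  boundary; slow swim: symmetric low-amplitude oscillation at 20-30 Hz),
* inhomogeneous-Poisson photon trains driven by motor activity through a
  single-exponential aequorin kernel,
* GCaMP6f-kernel fluorescence populations with out-of-focus contamination
  and two background ROIs,
* light-aligned current-clamp spike and voltage-clamp EPSC sweeps.

Determinism contract: identical (seed, parameters) produce bit-identical
output.  One global seed fans out to per-trial substreams through
``numpy.random.SeedSequence`` keyed on a per-modality stream id and the
trial counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .bioluminescence import smooth_signal, detect_signal
from .calcium import BehaviorEvent, CellRecord
from .ephys import ConnectivitySweep
from .kinematics import TailTrace

__all__ = [
    "GroundTruth",
    "gen_tail_trace",
    "gen_photon_train",
    "motor_drive",
    "gen_calcium_population",
    "gen_ephys_sweeps",
]

# fixed stream ids for seed fan-out
_STREAM = {"tail": 1, "photon": 2, "calcium": 3, "ephys": 4}


def substream(seed: int, stream: str, trial: int = 0) -> np.random.Generator:
    """Deterministic per-trial random generator derived from a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAM[stream], int(trial)])
    )


@dataclass
class GroundTruth:
    """Generator parameters and derived quantities for one trial."""

    kind: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    derived: dict[str, Any] = field(default_factory=dict)


# --------------------------------------------------------------------------
# tail kinematics
# --------------------------------------------------------------------------

#: Escape defaults: initial C-bend ~90-100 deg, instantaneous frequency
#: decaying from the fast regime (~55 Hz at onset, fast-component mean in
#: the mid-40s) through 30 Hz into the slow regime (~24 Hz), amplitude
#: decaying concomitantly.
ESCAPE_DEFAULTS = dict(
    c_amp_deg=120.0,
    sustain_amp_deg=20.0,
    amp_tau_ms=10.0,
    f0_hz=55.0,
    f_slow_hz=24.0,
    freq_tau_ms=60.0,
    bout_ms=180.0,
    taper_tau_ms=8.0,
)

SWIM_DEFAULTS = dict(
    amp_deg=15.0,
    freq_hz=25.0,
    bout_ms=180.0,
    taper_tau_ms=8.0,
)

PRE_STIM_MS = 200.0
POST_STIM_MS = 800.0
SPEED_GAIN = 0.06  # mm/s per (deg * Hz); calibrated for ~10 mm escape paths


def _escape_waveform(t_ms: np.ndarray, p: dict[str, float]) -> np.ndarray:
    """Noiseless escape tail angle on a post-stimulus time grid (ms)."""
    f_slow = p["f_slow_hz"] / 1000.0  # cycles/ms
    f0 = p["f0_hz"] / 1000.0
    tau = p["freq_tau_ms"]
    phase = 2 * np.pi * (f_slow * t_ms + (f0 - f_slow) * tau * (1 - np.exp(-t_ms / tau)))
    amp = p["c_amp_deg"] * np.exp(-t_ms / p["amp_tau_ms"]) + p["sustain_amp_deg"]
    taper = np.where(
        t_ms <= p["bout_ms"], 1.0, np.exp(-(t_ms - p["bout_ms"]) / p["taper_tau_ms"])
    )
    return amp * taper * np.sin(phase)


def _swim_waveform(t_ms: np.ndarray, p: dict[str, float]) -> np.ndarray:
    phase = 2 * np.pi * p["freq_hz"] / 1000.0 * t_ms
    taper = np.where(
        t_ms <= p["bout_ms"], 1.0, np.exp(-(t_ms - p["bout_ms"]) / p["taper_tau_ms"])
    )
    return p["amp_deg"] * taper * np.sin(phase)


def _noiseless_peaks(clean_post: np.ndarray) -> np.ndarray:
    """Frame indices (relative to stimulus) of extrema of the clean waveform."""
    d = np.diff(clean_post)
    sign_change = np.flatnonzero(np.sign(d[1:]) * np.sign(d[:-1]) < 0) + 1
    # keep extrema with non-negligible amplitude
    return sign_change[np.abs(clean_post[sign_change]) > 1.0]


def gen_tail_trace(
    kind: str,
    seed: int,
    trial: int = 0,
    fps: float = 650.0,
    noise_sd_deg: float = 0.05,
    with_head: bool = True,
    jitter: bool = True,
    **overrides: float,
) -> tuple[TailTrace, GroundTruth]:
    """Generate one tail-angle trial of the given maneuver class.

    ``kind`` is ``"escape"`` or ``"slow_swim"``.  Per-trial parameter
    jitter (drawn from the trial substream) can be disabled for exact
    reproducible waveforms.  Ground truth carries the waveform parameters
    plus derived quantities: noiseless peak frames, hemi-periods, mean
    tail-beat frequency and — for escapes — the time at which the
    instantaneous frequency crosses 30 Hz.
    """
    rng = substream(seed, "tail", trial)
    if kind == "escape":
        p = dict(ESCAPE_DEFAULTS)
    elif kind == "slow_swim":
        p = dict(SWIM_DEFAULTS)
    else:
        raise ValueError(f"unknown maneuver class {kind!r}")
    p.update(overrides)
    if jitter:
        if kind == "escape":
            p["c_amp_deg"] *= rng.uniform(0.85, 1.15)
            p["f0_hz"] += rng.uniform(-4.0, 4.0)
            p["f_slow_hz"] += rng.uniform(-2.0, 2.0)
            p["bout_ms"] *= rng.uniform(0.85, 1.15)
        else:
            p["amp_deg"] *= rng.uniform(0.8, 1.15)
            p["freq_hz"] = rng.uniform(22.0, 28.0)
            p["bout_ms"] *= rng.uniform(0.7, 1.3)

    n_pre = int(round(PRE_STIM_MS * fps / 1000.0))
    n_post = int(round(POST_STIM_MS * fps / 1000.0))
    t_ms = np.arange(n_post) / fps * 1000.0
    clean_post = (
        _escape_waveform(t_ms, p) if kind == "escape" else _swim_waveform(t_ms, p)
    )
    clean = np.concatenate([np.zeros(n_pre), clean_post])
    angle = clean + rng.normal(0.0, noise_sd_deg, len(clean))

    # derived ground truth from the noiseless waveform
    pk = _noiseless_peaks(clean_post)
    hemi = np.diff(pk)
    mean_tbf = float(np.mean(fps / (2.0 * hemi))) if len(hemi) else None
    derived: dict[str, Any] = {
        "peak_frames_post_stim": pk,
        "hemi_periods_frames": hemi,
        "mean_tbf_hz": mean_tbf,
        "first_peak_deg": float(clean_post[pk[0]]) if len(pk) else None,
    }
    if kind == "escape":
        # frequency crosses the cutoff where f_slow + (f0-f_slow) e^(-t/tau) = 30
        num = p["f0_hz"] - p["f_slow_hz"]
        den = 30.0 - p["f_slow_hz"]
        t_cross = p["freq_tau_ms"] * np.log(num / den) if den > 0 else None
        derived["transition_ms"] = t_cross
        derived["transition_frames_post_stim"] = (
            t_cross * fps / 1000.0 if t_cross is not None else None
        )

    head = None
    if with_head:
        # instantaneous envelope x frequency drives forward speed
        if kind == "escape":
            f_hz = p["f_slow_hz"] + (p["f0_hz"] - p["f_slow_hz"]) * np.exp(
                -t_ms / p["freq_tau_ms"]
            )
            amp = p["c_amp_deg"] * np.exp(-t_ms / p["amp_tau_ms"]) + p["sustain_amp_deg"]
        else:
            f_hz = np.full_like(t_ms, p["freq_hz"])
            amp = np.full_like(t_ms, p["amp_deg"])
        taper = np.where(
            t_ms <= p["bout_ms"],
            1.0,
            np.exp(-(t_ms - p["bout_ms"]) / p["taper_tau_ms"]),
        )
        speed = SPEED_GAIN * amp * taper * f_hz / 1000.0  # mm per ms
        heading = rng.uniform(0, 2 * np.pi)
        step = speed / fps * 1000.0  # mm per frame
        dx = np.cumsum(step) * np.cos(heading)
        dy = np.cumsum(step) * np.sin(heading)
        head = np.zeros((n_pre + n_post, 2))
        head[n_pre:, 0] = dx
        head[n_pre:, 1] = dy
        derived["path_length_mm"] = float(np.sum(step))

    trace = TailTrace(
        angle=angle,
        fps=fps,
        stim_frame=n_pre,
        head_xy=head,
        larva_id=f"sim{seed}",
        trial_id=f"{kind}_{trial}",
    )
    return trace, GroundTruth(kind=kind, seed=seed, params=p, derived=derived)


# --------------------------------------------------------------------------
# bioluminescence photon trains
# --------------------------------------------------------------------------

AEQUORIN_TAU_MS = 500.0
PHOTON_BASELINE_RATE = 0.05  # photons/ms
#: Gain calibrated so the default escape drive peaks near 30 photons/10 ms
#: after binning and smoothing, the scale of real escape signals.
PHOTON_GAIN = 60.0
DRIVE_TAU_MS = 30.0
#: Motor-drive amplitudes per maneuver class; the escape drive is several
#: times the swim drive, mirroring the stronger motor-pool recruitment of
#: real escapes (swim-class signals land near the ~4 photons/10 ms
#: detection floor of the differential start rule).
DRIVE_AMP = {"escape": 1.0, "slow_swim": 0.15}


def motor_drive(
    kind: str,
    n_ms: int,
    stim_ms: int,
    bout_ms: float = 180.0,
    amplitude: float | None = None,
    tau_ms: float = DRIVE_TAU_MS,
) -> np.ndarray:
    """Motor-activity trace (arbitrary units per ms) for one trial.

    Front-loaded exponential envelope over the bout: motor output is
    maximal at response onset (the fast component) and decays with
    ``tau_ms``, vanishing at bout end.
    """
    if amplitude is None:
        amplitude = DRIVE_AMP[kind]
    t = np.arange(n_ms, dtype=float)
    drive = np.zeros(n_ms)
    m = (t >= stim_ms) & (t < stim_ms + bout_ms)
    drive[m] = amplitude * np.exp(-(t[m] - stim_ms) / tau_ms)
    return drive


def gen_photon_train(
    drive: np.ndarray,
    seed: int,
    trial: int = 0,
    baseline_rate: float = PHOTON_BASELINE_RATE,
    gain: float = PHOTON_GAIN,
    kernel_tau_ms: float = AEQUORIN_TAU_MS,
    stim_ms: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Inhomogeneous-Poisson 1 ms photon counts from a motor-drive trace.

    The expected rate is ``baseline_rate + gain * (drive (*) kernel)`` with
    a unit-area single-exponential aequorin kernel.  Ground truth stores
    the exact rate profile and the noiseless processed signal (the same
    binning/smoothing applied to the expected counts), whose amplitude and
    time-to-peak are the reference values for detector-recovery checks.
    """
    drive = np.asarray(drive, dtype=float)
    if baseline_rate < 0 or gain < 0:
        raise ValueError("rates must be non-negative")
    rng = substream(seed, "photon", trial)
    t = np.arange(0, 6 * kernel_tau_ms)
    kernel = np.exp(-t / kernel_tau_ms)
    kernel /= kernel.sum()
    rate = baseline_rate + gain * np.convolve(drive, kernel)[: len(drive)]
    if np.any(rate < 0):
        raise ValueError("negative photon rate")
    counts = rng.poisson(rate)

    derived: dict[str, Any] = {"rate_per_ms": rate}
    if stim_ms is not None:
        # noiseless reference: process the expected rate directly
        exp_binned = rate[: (len(rate) // 10) * 10].reshape(-1, 10).sum(axis=1)
        smoothed = smooth_signal(exp_binned, 10)
        processed = np.maximum(smoothed - baseline_rate * 10.0, 0.0)
        ref = detect_signal(processed, stim_ms // 10)
        if ref is not None:
            derived.update(
                amplitude=ref.amplitude,
                time_to_peak_ms=ref.time_to_peak_ms,
                start_ms=ref.start_ms,
                peak_ms=ref.peak_ms,
            )
    gt = GroundTruth(
        kind="photon",
        seed=seed,
        params=dict(
            baseline_rate=baseline_rate, gain=gain, kernel_tau_ms=kernel_tau_ms
        ),
        derived=derived,
    )
    return counts, gt


# --------------------------------------------------------------------------
# calcium imaging populations
# --------------------------------------------------------------------------

CA_FS_HZ = 20.0
CA_RISE_MS = 50.0
CA_DECAY_MS = 400.0


def _gcamp_kernel(fs_hz: float, rise_ms: float = CA_RISE_MS, decay_ms: float = CA_DECAY_MS) -> np.ndarray:
    """Difference-of-exponentials GCaMP6f impulse response, unit peak."""
    t = np.arange(0, 5 * decay_ms / 1000.0, 1.0 / fs_hz)
    k = np.exp(-t / (decay_ms / 1000.0)) - np.exp(-t / (rise_ms / 1000.0))
    return k / k.max()


def gen_calcium_population(
    seed: int,
    n_cells: int = 69,
    n_swim_recruited: int = 16,
    n_escape_recruited: int = 61,
    n_swim_events: int = 4,
    n_escape_events: int = 2,
    fs_hz: float = CA_FS_HZ,
    contamination_dff: float = 20.0,
    bg_contamination_scale: float = 1.5,
    noise_sd: float = 1.0,
    f0: float = 100.0,
) -> tuple[list[CellRecord], np.ndarray, np.ndarray, list[BehaviorEvent], GroundTruth]:
    """Generate a motor-neuron population with known recruitment.

    Swim-recruited cells sit ventrally (dv_norm in [0.05, 0.30]); cells
    recruited only in escapes sit more dorsally ([0.45, 0.95]) and carry
    larger transients, so the directional recruitment properties (higher
    active proportion and higher mean dorso-ventral position in escapes)
    hold by construction on every seed.  Every swim-recruited cell is also
    escape-recruited.  Out-of-focus contamination is added to all cell
    traces and, scaled by ``bg_contamination_scale`` (the background ROIs
    are placed where out-of-focus light is strongest), to the two
    background ROIs.

    Returns ``(cells, background_ventral, background_dorsal, events,
    ground_truth)``.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if not (n_swim_recruited <= n_escape_recruited <= n_cells):
        raise ValueError("recruitment counts must nest within the population")
    if contamination_dff < 0:
        raise ValueError("contamination must be non-negative")
    rng = substream(seed, "calcium", 0)

    # event schedule: one event every 8 s, swims first
    gap = int(8 * fs_hz)
    events: list[BehaviorEvent] = []
    frame = int(2 * fs_hz)
    for i in range(n_swim_events):
        events.append(BehaviorEvent(f"swim{i}", "swim", frame, frame + int(fs_hz)))
        frame += gap
    for i in range(n_escape_events):
        events.append(BehaviorEvent(f"escape{i}", "escape", frame, frame + int(fs_hz)))
        frame += gap
    n_frames = frame + int(2 * fs_hz)

    swim_ids = np.arange(n_swim_recruited)
    escape_ids = np.arange(n_escape_recruited)  # includes all swim cells
    dv = np.empty(n_cells)
    dv[:n_swim_recruited] = rng.uniform(0.05, 0.30, n_swim_recruited)
    dv[n_swim_recruited:n_escape_recruited] = rng.uniform(
        0.45, 0.95, n_escape_recruited - n_swim_recruited
    )
    dv[n_escape_recruited:] = rng.uniform(0.05, 0.95, n_cells - n_escape_recruited)

    kernel = _gcamp_kernel(fs_hz)
    dff_clean = np.zeros((n_cells, n_frames))
    contam = np.zeros(n_frames)
    truth_active: dict[str, set[int]] = {}
    for ev in events:
        recruited = swim_ids if ev.kind == "swim" else escape_ids
        truth_active[ev.event_id] = set(int(i) for i in recruited)
        impulse_frame = ev.onset_frame + 1
        span = min(len(kernel), n_frames - impulse_frame)
        # out-of-focus light scales with how much of the population fires:
        # escapes light up the whole field, swims roughly half as much
        contam_scale = 0.5 if ev.kind == "swim" else 1.0
        contam[impulse_frame : impulse_frame + span] += (
            contamination_dff * contam_scale * kernel[:span]
        )
        for i in recruited:
            if ev.kind == "swim":
                amp = 20.0 + 30.0 * dv[i]
            else:
                amp = 40.0 + 80.0 * dv[i]
            amp *= rng.uniform(0.9, 1.1)
            dff_clean[i, impulse_frame : impulse_frame + span] += amp * kernel[:span]

    cells: list[CellRecord] = []
    for i in range(n_cells):
        f = f0 * (1.0 + (dff_clean[i] + contam) / 100.0)
        f = f + rng.normal(0.0, noise_sd, n_frames)
        cells.append(
            CellRecord(
                roi_id=f"roi{i:03d}", fluorescence=f, dv_raw=dv[i], dv_norm=dv[i]
            )
        )
    bg_contam = bg_contamination_scale * contam
    bg_ventral = f0 * (1.0 + bg_contam / 100.0) + rng.normal(0.0, noise_sd, n_frames)
    bg_dorsal = f0 * (1.0 + bg_contam / 100.0) + rng.normal(0.0, noise_sd, n_frames)

    gt = GroundTruth(
        kind="calcium",
        seed=seed,
        params=dict(
            n_cells=n_cells,
            n_swim_recruited=n_swim_recruited,
            n_escape_recruited=n_escape_recruited,
            contamination_dff=contamination_dff,
            noise_sd=noise_sd,
        ),
        derived=dict(
            dv_norm=dv,
            active_by_event=truth_active,
            swim_cells=set(int(i) for i in swim_ids),
            escape_cells=set(int(i) for i in escape_ids),
        ),
    )
    return cells, bg_ventral, bg_dorsal, events, gt


# --------------------------------------------------------------------------
# optogenetic connectivity sweeps
# --------------------------------------------------------------------------

EPHYS_FS_HZ = 10_000.0
SPIKE_LATENCY_MS = 2.80
EPSC_LATENCY_MS = 3.71
EPSC_AMP_PA = 28.14
REST_MV = -65.0


def _alpha(t_ms: np.ndarray, tau_ms: float = 1.0) -> np.ndarray:
    """Unit-peak alpha function, zero for t < 0."""
    x = np.where(t_ms > 0, t_ms / tau_ms, 0.0)
    return np.where(t_ms > 0, x * np.exp(1.0 - x), 0.0)


def gen_ephys_sweeps(
    seed: int,
    n_stim: int = 10,
    spike_latency_ms: float = SPIKE_LATENCY_MS,
    epsc_latency_ms: float = EPSC_LATENCY_MS,
    epsc_amp_pa: float = EPSC_AMP_PA,
    spike_amp_mv: float = 90.0,
    spike_jitter_ms: float = 0.0,
    epsc_jitter_ms: float = 0.0,
    noise_sd_cc_mv: float = 0.3,
    noise_sd_vc_pa: float = 1.0,
    pulse_duration_ms: float = 5.0,
    fs_hz: float = EPHYS_FS_HZ,
) -> tuple[ConnectivitySweep, ConnectivitySweep, GroundTruth]:
    """Paired current-clamp (RB spike) and voltage-clamp (V2a EPSC) sweeps.

    Each of ``n_stim`` light pulses (spaced 100 ms) elicits one spike
    peaking ``spike_latency_ms`` after pulse onset in the cc sweep and one
    inward alpha-function EPSC starting ``epsc_latency_ms`` after onset in
    the vc sweep, with optional per-stimulation Gaussian latency jitter.
    """
    if spike_latency_ms <= 0 or epsc_latency_ms <= 0:
        raise ValueError("latencies must be positive")
    if epsc_amp_pa < 0:
        raise ValueError("EPSC amplitude must be non-negative")
    rng = substream(seed, "ephys", 0)
    pulse_onsets = [100.0 + 100.0 * i for i in range(n_stim)]
    n = int((pulse_onsets[-1] + 100.0) * fs_hz / 1000.0)
    t_ms = np.arange(n) / fs_hz * 1000.0

    spike_lats = spike_latency_ms + rng.normal(0.0, spike_jitter_ms, n_stim)
    epsc_lats = epsc_latency_ms + rng.normal(0.0, epsc_jitter_ms, n_stim)

    cc = np.full(n, REST_MV)
    for onset, lat in zip(pulse_onsets, spike_lats):
        cc += spike_amp_mv * np.exp(-0.5 * ((t_ms - onset - lat) / 0.4) ** 2)
    cc += rng.normal(0.0, noise_sd_cc_mv, n)

    vc = np.zeros(n)
    for onset, lat in zip(pulse_onsets, epsc_lats):
        vc -= epsc_amp_pa * _alpha(t_ms - onset - lat)
    vc += rng.normal(0.0, noise_sd_vc_pa, n)

    cc_sweep = ConnectivitySweep(
        trace=cc, fs_hz=fs_hz, pulse_onsets_ms=pulse_onsets,
        pulse_duration_ms=pulse_duration_ms, mode="cc", cell_id="rb",
    )
    vc_sweep = ConnectivitySweep(
        trace=vc, fs_hz=fs_hz, pulse_onsets_ms=pulse_onsets,
        pulse_duration_ms=pulse_duration_ms, mode="vc", cell_id="v2a",
    )
    gt = GroundTruth(
        kind="ephys",
        seed=seed,
        params=dict(
            spike_latency_ms=spike_latency_ms,
            epsc_latency_ms=epsc_latency_ms,
            epsc_amp_pa=epsc_amp_pa,
        ),
        derived=dict(spike_latencies_ms=spike_lats, epsc_latencies_ms=epsc_lats),
    )
    return cc_sweep, vc_sweep, gt
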