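"""End-to-end replication studies on synthetic recordings.

Each function generates a batch of synthetic trials with known ground
truth, runs the corresponding analysis chain, and reports recovery
statistics: maneuver-classification accuracy and tail-beat-frequency
error, fast-to-slow transition localization, Poisson baseline-rate
recovery, exponential-decay refitting, calcium active/silent recovery
with its dorso-ventral ordering, and EPSC detector bias.  These are the
quantitative checks behind the package's test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import kinematics as kin
from .bioluminescence import PhotonTrace, detect_signal, estimate_baseline, fit_decay, process_trace
from .calcium import classify_active, recruitment_summary
from .ephys import compute_lag, detect_epsc, detect_spike_ttp
from .synthetic import gen_calcium_population, gen_ephys_sweeps, gen_tail_trace

__all__ = [
    "analyze_tail_trace",
    "maneuver_recovery_study",
    "trial_composition_study",
    "recruitment_study",
    "baseline_recovery_study",
    "decay_recovery_study",
    "calcium_recovery_study",
    "epsc_detector_study",
    "lag_study",
]

#: Median window for the 650 fps freely-swimming analysis (the 10-frame
#: published window belongs to the 1000 fps head-embedded assay).
SMOOTH_WINDOW_650 = 3


def analyze_tail_trace(trace: kin.TailTrace, smooth_window: int = SMOOTH_WINDOW_650) -> dict:
    """Full single-trial kinematic analysis: bout, peaks, category, split."""
    sm = kin.smooth_tail_angle(trace, smooth_window)
    bout = kin.detect_bout(sm)
    if bout is None:
        return {"category": "unclassified", "bout": None}
    peaks = kin.detect_peaks(sm, bout)
    category = kin.classify_maneuver(bout, peaks)
    summary = kin.kinematic_summary(sm, bout, peaks, category)
    kept, reason = kin.exclude_trial(sm, peaks)
    out = {
        "bout": bout,
        "peaks": peaks,
        "category": category,
        "summary": summary,
        "kept": kept,
        "exclusion_reason": reason,
    }
    if len(peaks) >= 2:
        frames = np.array([f for f, _ in peaks]) - trace.stim_frame
        hemi = np.diff(frames)
        comp = kin.split_fast_slow(hemi, trace.fps)
        out["peak_frames_post_stim"] = frames
        out["component"] = comp
    return out


def maneuver_recovery_study(seed: int, n_per_class: int = 200) -> dict:
    """Classification, TBF and transition recovery on synthetic bouts.

    Generates ``n_per_class`` escapes and slow swims at the generator
    defaults, analyzes each end to end, and compares with ground truth.
    The transition error is the distance (frames) between the start of
    the first slow-labeled hemi-period and the generated frequency
    crossing of 30 Hz, reported relative to the local hemi-period.
    """
    n_correct = {"escape": 0, "slow_swim": 0}
    tbf_errs: list[float] = []
    trans_err_frames: list[float] = []
    trans_hemi: list[float] = []
    for trial in range(n_per_class):
        for kind in ("escape", "slow_swim"):
            trace, gt = gen_tail_trace(kind, seed, trial=trial)
            res = analyze_tail_trace(trace)
            if res["category"] == kind:
                n_correct[kind] += 1
            summ = res.get("summary")
            if summ is not None and summ.mean_tbf_hz and gt.derived["mean_tbf_hz"]:
                tbf_errs.append(
                    abs(summ.mean_tbf_hz - gt.derived["mean_tbf_hz"])
                    / gt.derived["mean_tbf_hz"]
                )
            if kind == "escape" and "component" in res:
                labels = res["component"].labels
                if "slow" in labels:
                    i = labels.index("slow")
                    frames = res["peak_frames_post_stim"]
                    hemi = np.diff(frames)
                    trans_err_frames.append(
                        abs(float(frames[i]) - gt.derived["transition_frames_post_stim"])
                    )
                    trans_hemi.append(float(hemi[i]))
    return {
        "n_per_class": n_per_class,
        "accuracy_pct": 100.0 * sum(n_correct.values()) / (2 * n_per_class),
        "accuracy_escape_pct": 100.0 * n_correct["escape"] / n_per_class,
        "accuracy_swim_pct": 100.0 * n_correct["slow_swim"] / n_per_class,
        "mean_tbf_error_pct": 100.0 * float(np.mean(tbf_errs)),
        "max_tbf_error_pct": 100.0 * float(np.max(tbf_errs)),
        "transition_mean_error_frames": float(np.mean(trans_err_frames)),
        "transition_mean_hemi_frames": float(np.mean(trans_hemi)),
        "transition_error_hemi_periods": float(
            np.mean(trans_err_frames) / np.mean(trans_hemi)
        ),
    }


def trial_composition_study(seed: int, n_trials: int = 283, n_swims: int = 21) -> dict:
    """Classify a trial battery with the study's swim/escape composition.

    Generates ``n_swims`` slow swims among ``n_trials`` acoustic trials
    (the remainder escapes) and reports the percentage classified as slow
    swims by the automated categorization.
    """
    n_slow = 0
    for trial in range(n_trials):
        kind = "slow_swim" if trial < n_swims else "escape"
        trace, _ = gen_tail_trace(kind, seed, trial=trial)
        if analyze_tail_trace(trace)["category"] == "slow_swim":
            n_slow += 1
    return {"n_trials": n_trials, "slow_swim_pct": 100.0 * n_slow / n_trials}


def recruitment_study(seed: int) -> dict:
    """Active/silent classification and recruitment on the default population."""
    cells, bgv, bgd, events, gt = gen_calcium_population(seed=seed)
    for ev in events:
        classify_active(cells, bgv, bgd, ev)
    summary = recruitment_summary(cells, events)
    return {
        "swim_active_pct": summary["swim"]["proportion_active_pct"],
        "escape_active_pct": summary["escape"]["proportion_active_pct"],
        "swim_mean_dv": summary["swim"]["mean_dv_norm"],
        "escape_mean_dv": summary["escape"]["mean_dv_norm"],
        "n_cells": int(summary["swim"]["n_total"]),
    }


def baseline_recovery_study(
    seed: int, rates_per_ms: tuple[float, ...] = (0.05, 0.2, 0.5), n_reps: int = 500
) -> dict:
    """Poisson baseline-rate estimator accuracy over seeded replicates."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    errs = {}
    for rate in rates_per_ms:
        ests = [
            estimate_baseline(PhotonTrace(rng.poisson(rate, 600), 500))
            for _ in range(n_reps)
        ]
        errs[rate] = 100.0 * abs(float(np.mean(ests)) - 10 * rate) / (10 * rate)
    return {"n_reps": n_reps, "per_rate_error_pct": errs,
            "max_error_pct": max(errs.values())}


def decay_recovery_study(seed: int) -> dict:
    """Exponential-decay refitting: noiseless recovery and the R^2 gate."""
    t = np.arange(0, 600, 10.0)
    clean = 20.0 * np.exp(-t / 80.0)
    k, r2 = fit_decay(clean, 0, len(clean) - 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    k_noise, r2_noise = fit_decay(rng.normal(0, 1, 30), 0, 29)
    return {
        "k_error_pct": 100.0 * abs(k - 1 / 80.0) / (1 / 80.0),
        "r2": r2,
        "noise_coefficient_excluded": k_noise is None,
        "noise_r2": r2_noise,
    }


def calcium_recovery_study(seed: int, n_seeds: int = 20) -> dict:
    """Perfect-recovery limit and directional recruitment across seeds.

    For each derived seed: a zero-noise/zero-contamination population must
    be recovered exactly, and on the default (noisy, contaminated)
    population the escape recruitment and its mean dorso-ventral position
    must exceed the swim values.
    """
    n_perfect = 0
    directional = True
    for i in range(n_seeds):
        sub = seed * 1000 + i
        cells, bgv, bgd, events, gt = gen_calcium_population(
            seed=sub, noise_sd=0.0, contamination_dff=0.0
        )
        exact = True
        for ev in events:
            flags = classify_active(cells, bgv, bgd, ev)
            got = {int(r[3:]) for r, f in flags.items() if f}
            if got != gt.derived["active_by_event"][ev.event_id]:
                exact = False
        n_perfect += exact

        rec = recruitment_study(sub)
        if not (
            rec["escape_active_pct"] > rec["swim_active_pct"]
            and rec["escape_mean_dv"] > rec["swim_mean_dv"]
        ):
            directional = False
    return {
        "n_seeds": n_seeds,
        "perfect_recovery_pct": 100.0 * n_perfect / n_seeds,
        "directional_ordering_all_seeds": directional,
    }


def epsc_detector_study(seed: int, n_sweeps: int = 200) -> dict:
    """EPSC onset bias and amplitude error at SNR well above 10."""
    onset_errs = []
    amp_errs = []
    for i in range(n_sweeps):
        cc, vc, gt = gen_ephys_sweeps(seed=seed * 1000 + i, n_stim=1)
        res = detect_epsc(vc, vc.pulse_onsets_ms[0])
        onset, amp = res
        onset_errs.append(onset - gt.params["epsc_latency_ms"])
        amp_errs.append(abs(amp - gt.params["epsc_amp_pa"]) / gt.params["epsc_amp_pa"])
    return {
        "n_sweeps": n_sweeps,
        "onset_bias_ms": float(np.mean(onset_errs)),
        "amp_error_pct": 100.0 * float(np.mean(amp_errs)),
    }


def lag_study(seed: int, n_stim: int = 20) -> dict:
    """Detect spikes and EPSCs on default synthetic sweeps and compute the lag."""
    cc, vc, _ = gen_ephys_sweeps(
        seed=seed, n_stim=n_stim, spike_jitter_ms=0.29, epsc_jitter_ms=0.19
    )
    ttps = [detect_spike_ttp(cc, o) for o in cc.pulse_onsets_ms]
    epscs = [detect_epsc(vc, o) for o in vc.pulse_onsets_ms]
    onsets = [o for o, _ in epscs if o is not None]
    return {
        "spike_ttp_ms": float(np.mean([t for t in ttps if t is not None])),
        "epsc_onset_ms": float(np.mean(onsets)),
        "lag_ms": compute_lag([t for t in ttps if t is not None], onsets),
    }
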