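"""Stage orchestration: simulate, analyze, and write result tables.

``run_pipeline`` executes the requested stages in dependency order.
Every output CSV carries the config hash and seed in a sidecar manifest;
a stage whose outputs already exist under the same config hash is skipped,
so deleting one intermediate regenerates only the downstream stages.  A
stage-granular log records parameters and record counts in/out so the
exclusion criteria are auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioluminescence as biolum
from . import kinematics as kin
from .config import PipelineConfig
from .io import write_table
from .synthetic import gen_photon_train, gen_tail_trace, motor_drive

log = logging.getLogger("escapekit")

STAGE_ORDER = ["simulate", "kinematics", "biolum"]


def _manifest_path(out: Path, stage: str) -> Path:
    return out / f"{stage}.manifest.json"


def _stage_fresh(out: Path, stage: str, cfg_hash: str, outputs: list[Path]) -> bool:
    man = _manifest_path(out, stage)
    if not man.exists() or not all(p.exists() for p in outputs):
        return False
    try:
        return json.loads(man.read_text())["config_hash"] == cfg_hash
    except (json.JSONDecodeError, KeyError):
        return False


def _write_manifest(out: Path, stage: str, cfg: PipelineConfig, n_records: int) -> None:
    _manifest_path(out, stage).write_text(
        json.dumps(
            {"stage": stage, "config_hash": cfg.config_hash(), "seed": cfg.seed,
             "n_records": n_records},
            indent=2,
        )
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the configured stages; returns stage -> primary output path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    results: dict[str, Path] = {}

    stages = [s for s in STAGE_ORDER if s in config.stages]
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    for stage in stages:
        if stage == "simulate":
            results[stage] = _stage_simulate(config, out, cfg_hash)
        elif stage == "kinematics":
            results[stage] = _stage_kinematics(config, out, cfg_hash)
        elif stage == "biolum":
            results[stage] = _stage_biolum(config, out, cfg_hash)
    return results


def _stage_simulate(cfg: PipelineConfig, out: Path, cfg_hash: str) -> Path:
    tail_path = out / "tail_traces.csv"
    photon_path = out / "photon_trains.csv"
    if _stage_fresh(out, "simulate", cfg_hash, [tail_path, photon_path]):
        log.info("simulate: up to date, skipping")
        return tail_path

    rows = []
    photon_rows = []
    n = cfg.synthetic.n_trials
    for trial in range(n):
        kind = "escape" if trial % 2 == 0 else "slow_swim"
        trace, gt = gen_tail_trace(
            kind, cfg.seed, trial=trial, fps=cfg.synthetic.fps,
            noise_sd_deg=cfg.synthetic.noise_sd_deg,
        )
        frames = np.arange(len(trace.angle))
        rows.append(
            pd.DataFrame(
                {
                    "larva_id": trace.larva_id,
                    "trial_id": trace.trial_id,
                    "frame": frames,
                    "angle_deg": trace.angle,
                    "head_x_mm": trace.head_xy[:, 0],
                    "head_y_mm": trace.head_xy[:, 1],
                    "fps": trace.fps,
                    "stim_frame": trace.stim_frame,
                }
            )
        )
        n_ms, stim_ms = 3000, 500
        drive = motor_drive(kind, n_ms, stim_ms)
        counts, _ = gen_photon_train(drive, cfg.seed, trial=trial, stim_ms=stim_ms)
        photon_rows.append(
            pd.DataFrame(
                {
                    "larva_id": trace.larva_id,
                    "trial_id": trace.trial_id,
                    "time_ms": np.arange(n_ms),
                    "photon_count": counts,
                    "stim_time_ms": stim_ms,
                }
            )
        )
    write_table(pd.concat(rows, ignore_index=True), tail_path)
    write_table(pd.concat(photon_rows, ignore_index=True), photon_path)
    _write_manifest(out, "simulate", cfg, n)
    log.info("simulate: wrote %d trials", n)
    return tail_path


def _stage_kinematics(cfg: PipelineConfig, out: Path, cfg_hash: str) -> Path:
    summary_path = out / "kinematic_summary.csv"
    hemi_path = out / "hemi_period_labels.csv"
    if _stage_fresh(out, "kinematics", cfg_hash, [summary_path, hemi_path]):
        log.info("kinematics: up to date, skipping")
        return summary_path

    k = cfg.kinematics
    df = pd.read_csv(out / "tail_traces.csv")
    summaries = []
    hemi_rows = []
    n_in = n_kept = 0
    for (larva, trial), g in df.groupby(["larva_id", "trial_id"], sort=False):
        n_in += 1
        trace = kin.TailTrace(
            angle=g["angle_deg"].to_numpy(),
            fps=float(g["fps"].iloc[0]),
            stim_frame=int(g["stim_frame"].iloc[0]),
            head_xy=g[["head_x_mm", "head_y_mm"]].to_numpy()
            if "head_x_mm" in g
            else None,
            larva_id=str(larva),
            trial_id=str(trial),
        )
        smoothed = kin.smooth_tail_angle(trace, k.smooth_window)
        bout = kin.detect_bout(
            smoothed, k.start_diff_thresh, k.n_confirm, k.quiet_thresh, k.quiet_len
        )
        if bout is None:
            continue
        peaks = kin.detect_peaks(
            smoothed, bout, k.min_sep_ms, k.min_rise_deg, k.lookback_ms
        )
        category = kin.classify_maneuver(bout, peaks, k.asym_ratio, k.slow_amp_max_deg)
        summ = kin.kinematic_summary(smoothed, bout, peaks, category)
        kept, reason = kin.exclude_trial(
            smoothed, peaks, k.max_latency_frames, k.min_first_peak_deg,
            k.start_diff_thresh, k.n_confirm,
        )
        n_kept += kept
        summaries.append(
            {
                "larva_id": larva,
                "trial_id": trial,
                "config_hash": cfg_hash,
                "category": category,
                "duration_ms": summ.duration_ms,
                "n_oscillations": summ.n_oscillations,
                "mean_tbf_hz": summ.mean_tbf_hz,
                "distance_mm": summ.distance_mm,
                "speed_mm_s": summ.speed_mm_s,
                "first_peak_amplitude_deg": summ.first_peak_amplitude_deg,
                "first_peak_latency_frames": summ.first_peak_latency_frames,
                "kept": kept,
                "exclusion_reason": reason,
            }
        )
        if len(peaks) >= 2:
            hemi = np.diff([f for f, _ in peaks])
            comp = kin.split_fast_slow(hemi, trace.fps, k.cutoff_hz)
            for i, (h, lab) in enumerate(zip(comp.hemi_periods, comp.labels)):
                hemi_rows.append(
                    {
                        "larva_id": larva,
                        "trial_id": trial,
                        "config_hash": cfg_hash,
                        "hemi_index": i,
                        "hemi_period_frames": h,
                        "label": lab,
                    }
                )
    write_table(pd.DataFrame(summaries), summary_path)
    write_table(pd.DataFrame(hemi_rows), hemi_path)
    _write_manifest(out, "kinematics", cfg, len(summaries))
    log.info("kinematics: %d trials in, %d kept by exclusion criteria", n_in, n_kept)
    return summary_path


def _stage_biolum(cfg: PipelineConfig, out: Path, cfg_hash: str) -> Path:
    sig_path = out / "bioluminescence_signals.csv"
    if _stage_fresh(out, "biolum", cfg_hash, [sig_path]):
        log.info("biolum: up to date, skipping")
        return sig_path

    b = cfg.bioluminescence
    df = pd.read_csv(out / "photon_trains.csv")
    rows = []
    for (larva, trial), g in df.groupby(["larva_id", "trial_id"], sort=False):
        trace = biolum.PhotonTrace(
            counts_1ms=g["photon_count"].to_numpy(),
            stim_time_ms=int(g["stim_time_ms"].iloc[0]),
            larva_id=str(larva),
            trial_id=str(trial),
        )
        processed, rate, stim_bin = biolum.process_trace(trace, b.bin_ms, b.smooth_window)
        sig = biolum.detect_signal(processed, stim_bin, b.bin_ms, b.start_diff, b.end_diff)
        row = {"larva_id": larva, "trial_id": trial, "config_hash": cfg_hash,
               "baseline_rate_per_10ms": rate}
        if sig is not None:
            peak_bin = int(sig.peak_ms) // b.bin_ms
            end_bin = int(sig.end_ms) // b.bin_ms
            if end_bin - peak_bin >= 5:
                k_coef, r2 = biolum.fit_decay(processed, peak_bin, end_bin, b.bin_ms, b.r2_gate)
                sig.decay_coef, sig.decay_r2 = k_coef, r2
            row.update(
                start_ms=sig.start_ms, peak_ms=sig.peak_ms, end_ms=sig.end_ms,
                amplitude=sig.amplitude, time_to_peak_ms=sig.time_to_peak_ms,
                snr=sig.snr, decay_coef=sig.decay_coef, decay_r2=sig.decay_r2,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if "amplitude" in table:
        table["normalized_amplitude"] = biolum.normalize_per_larva(table)
    write_table(table, sig_path)
    _write_manifest(out, "biolum", cfg, len(rows))
    log.info("biolum: %d trials processed", len(rows))
    return sig_path
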