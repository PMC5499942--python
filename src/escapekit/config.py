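"""Pipeline configuration: every threshold with units, validated strictly.

``PipelineConfig`` collects the defaults of all analysis stages.  Unknown
keys are rejected, all thresholds must be positive, and a config
round-trips unchanged through JSON, so (config, seed) fully determines a
pipeline run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "KinematicsConfig",
    "BioluminescenceConfig",
    "CalciumConfig",
    "EphysConfig",
    "SyntheticConfig",
    "PipelineConfig",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class KinematicsConfig(_Strict):
    fps: float = Field(650.0, gt=0, description="frames per second")
    smooth_window: int = Field(
        3, ge=1,
        description="median filter window, frames (use 10 for the 1000 fps "
        "head-embedded assay; at 650 fps a 10-frame window spans a fast "
        "half-period and crushes C-bends)",
    )
    start_diff_thresh: float = Field(0.08, gt=0, description="deg/frame")
    n_confirm: int = Field(3, ge=1, description="confirmation frames for bout start")
    quiet_thresh: float = Field(0.1, gt=0, description="deg/frame")
    quiet_len: int = Field(20, ge=1, description="quiet frames ending a bout")
    min_sep_ms: float = Field(2.0, gt=0, description="min peak separation, ms")
    min_rise_deg: float = Field(1.0, gt=0, description="min rise over lookback, deg")
    lookback_ms: float = Field(5.0, gt=0, description="peak lookback, ms")
    asym_ratio: float = Field(1.5, gt=0, description="C-bend asymmetry ratio")
    slow_amp_max_deg: float = Field(25.0, gt=0, description="slow-swim peak cap, deg")
    cutoff_hz: float = Field(30.0, gt=0, description="fast/slow cycle cutoff, Hz")
    max_latency_frames: int = Field(20, ge=1, description="exclusion criterion (ii)")
    min_first_peak_deg: float = Field(60.0, gt=0, description="exclusion criterion (iii)")


class BioluminescenceConfig(_Strict):
    bin_ms: int = Field(10, ge=1, description="photon binning, ms")
    smooth_window: int = Field(10, ge=1, description="running-average window, bins")
    start_diff: float = Field(0.4, gt=0, description="photons/10 ms per bin")
    end_diff: float = Field(0.2, gt=0, description="photons/10 ms per bin")
    r2_gate: float = Field(0.95, gt=0, le=1, description="decay-fit R^2 gate")


class CalciumConfig(_Strict):
    fs_hz: float = Field(20.0, gt=0, description="imaging frame rate")
    f0_window_frames: int = Field(20, ge=1, description="baseline window, frames")
    noise_max_mv: float = Field(0.05, gt=0, description="VNR noise QC cap, mV")
    snr_min: float = Field(3.0, gt=0, description="VNR event SNR floor")


class EphysConfig(_Strict):
    fs_hz: float = Field(10_000.0, gt=0)
    spike_threshold_mv: float = Field(0.0, description="spike crossing, mV")
    k_sd: float = Field(3.0, gt=0, description="EPSC onset threshold, baseline SDs")
    n_confirm: int = Field(5, ge=1, description="EPSC confirmation samples")
    cutoff_ms: float = Field(3.0, gt=0, description="monosynaptic lag cutoff")
    synaptic_delay_ms: float = Field(0.5, gt=0, description="assumed synaptic delay")


class SyntheticConfig(_Strict):
    n_trials: int = Field(20, ge=1)
    noise_sd_deg: float = Field(0.05, ge=0, description="tail-angle noise SD, deg")
    fps: float = Field(650.0, gt=0)


class PipelineConfig(_Strict):
    seed: int = Field(0, ge=0)
    out_dir: str = "results"
    stages: list[str] = Field(default_factory=lambda: ["simulate", "kinematics"])
    kinematics: KinematicsConfig = Field(default_factory=KinematicsConfig)
    bioluminescence: BioluminescenceConfig = Field(default_factory=BioluminescenceConfig)
    calcium: CalciumConfig = Field(default_factory=CalciumConfig)
    ephys: EphysConfig = Field(default_factory=EphysConfig)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)

    def config_hash(self) -> str:
        """Stable short hash of the analysis parameters.

        The output directory is excluded: it changes where results land,
        not what they contain.
        """
        payload = self.model_dump()
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
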