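"""Run configuration with the analysis defaults frozen in one place."""

from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, Field, field_validator


class RunConfig(BaseModel):
    """All pipeline parameters; defaults are the analysis-standard values."""
    # paths
    data_dir: str = "dataset"
    out_dir: str = "results"
    # paradigm
    paradigm: str = "optogenetic"           # visual | optogenetic | blank
    # vessel_quant
    sample_spacing_um: float = 20.0
    profile_length_um: float = 70.0
    profile_points: int = 200
    parallel_sigma_um: float = 5.6
    # activity_map
    gcamp_kernel_um: float = 90.0
    evoked_window_s: float = 1.12
    activity_threshold: float = 0.5
    conservative_threshold: float = 0.2
    kernel_sigma_um: float = 400.0
    # trajectory_qc
    z_percentile: float = 96.0
    z_threshold: float = 3.0
    noise_band_hz: tuple[float, float] = (0.5, 1.3)
    noise_threshold_db: float = 3.0
    noise_window_s: float = 2.3
    slope_alpha: float = 0.01
    # kinetics
    velocity_spacing_um: float = 45.0
    onset_fraction: float = 0.1
    distance_bins_um: tuple[float, ...] = (0.0, 1.0, 400.0, 800.0, 1200.0, 1600.0, 2000.0)
    # simulation
    n_trials: int = 30
    seed: int = 0

    @field_validator("n_trials")
    @classmethod
    def _trials_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_trials must be >= 1")
        return v

    @field_validator("paradigm")
    @classmethod
    def _paradigm_known(cls, v: str) -> str:
        if v not in ("visual", "optogenetic", "blank"):
            raise ValueError("paradigm must be visual, optogenetic or blank")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
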