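"""Run configuration: validated, unit-explicit, serializable to YAML.

Every numeric key carries its unit in the name (``d_mm``, ``tau_us``) so a
config file round-trips bit-exactly across tools.  Seeds are mandatory for
the stochastic stages.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from . import presets

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class GeometryConfig(BaseModel):
    d_mm: float = 20.0
    aspect_ratio: float = 2.9
    dilation_ratio: float = 1.9
    total_length_mm: float = 250.0
    wall_thickness_mm: float = 1.8


class FluidConfig(BaseModel):
    kinematic_viscosity_mm2s: float = presets.KINEMATIC_VISCOSITY_MM2S
    density_kgm3: float = presets.BLOOD_ANALOG_DENSITY


class CameraConfig(BaseModel):
    rows_px: int = 544
    cols_px: int = 640
    scale_px_mm: float = presets.PIXEL_SCALE_IDEALIZED
    exposure_us: float = 13000.0
    min_interframe_us: float = 80.0


class PivConfig(BaseModel):
    passes_px: list[int] = Field(default_factory=lambda: [128, 64, 32])
    overlap: float = 0.5
    snr_min: float = 1.25
    global_k: float = 5.0
    median_k: float = 3.0


class SimulateConfig(BaseModel):
    n_cycles: int = 10
    flowmeter_delay_ms: float = 23.0
    lowpass_hz: float = 25.0


class GenerateConfig(BaseModel):
    n_cycles: int = 1
    pairs_per_cycle: int = presets.PAIRS_PER_CYCLE
    density_per_mm2: float = 7.0
    sheet_thickness_mm: float = 1.5
    cycle_jitter: float = 0.0


class RunConfig(BaseModel):
    """Top-level pipeline configuration."""

    flow_case: str = "FH"
    illumination: str = "C4"
    seed: int = 1
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    camera: CameraConfig = Field(default_factory=CameraConfig)
    piv: PivConfig = Field(default_factory=PivConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    generate: GenerateConfig = Field(default_factory=GenerateConfig)
    output_dir: str = "aaapiv_run"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.flow_case not in presets.FLOW_CASES:
            raise ValueError(f"unknown flow case {self.flow_case!r}")
        if self.illumination not in presets.ILLUMINATION_CONFIGS:
            raise ValueError(f"unknown illumination config {self.illumination!r}")
        if self.geometry.d_mm <= 0 or self.camera.scale_px_mm <= 0:
            raise ValueError("geometry and camera scales must be positive")
        if not 0 <= self.piv.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.simulate.flowmeter_delay_ms < 0:
            raise ValueError("flowmeter delay must be non-negative")
        return self


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical YAML serialization."""
    canon = yaml.safe_dump(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
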