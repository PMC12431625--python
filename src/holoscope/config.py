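"""Validated run configuration (YAML) for the command-line pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .acquisition import LEDGridPlan, plan_grid
from .optics import OpticalConfig
from .simulate import NoiseSpec

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticalSettings(_Strict):
    wavelength_um: float = 0.45
    camera_pixel_pitch_um: float = 2.4
    led_pitch_um: float = 4.0
    source_diameter_um: float = 1.0
    z_sample_sensor_um: float = 7000.0
    z_source_sample_um: float = 300.0
    sensor_shape: tuple[int, int] = (512, 512)

    def build(self) -> OpticalConfig:
        return OpticalConfig(
            wavelength=self.wavelength_um,
            camera_pixel_pitch=self.camera_pixel_pitch_um,
            led_pitch=self.led_pitch_um,
            source_diameter=self.source_diameter_um,
            z_sample_sensor=self.z_sample_sensor_um,
            z_source_sample=self.z_source_sample_um,
            sensor_shape=tuple(self.sensor_shape),
        )


class PlanSettings(_Strict):
    rows: int = 5
    cols: int = 5
    step_leds: int = 10
    center_led: tuple[int, int] = (240, 320)
    ordering: Literal["row_major", "serpentine"] = "row_major"

    def build(self, led_pitch_um: float) -> LEDGridPlan:
        return plan_grid(self.rows, self.cols, self.step_leds, led_pitch_um,
                         tuple(self.center_led), self.ordering)


class NoiseSettings(_Strict):
    photon_budget: float = 5000.0
    read_noise: float = 2.0
    ambient_offset: float = 20.0

    def build(self) -> NoiseSpec:
        return NoiseSpec(self.photon_budget, self.read_noise, self.ambient_offset)


class PhantomSettings(_Strict):
    kind: Literal["disks", "usaf", "edge"] = "disks"
    field_margin_px: int = 256  # padding beyond the sensor for LED shifts
    # disks
    n_disks: int = 25
    radius_min_um: float = 2.5
    radius_max_um: float = 4.0
    min_separation_um: Optional[float] = None
    # keep disk centres at least this far inside the imaged field of view
    # (objects near the window edge lose their fringes and reconstruct weakly)
    fov_margin_um: float = 0.0
    # usaf
    elements: list[tuple[int, int]] = Field(default_factory=lambda: [(7, 1), (7, 6)])
    # edge
    edge_width_um: float = 0.0


class SimulateSettings(_Strict):
    phantom: PhantomSettings = PhantomSettings()
    noise: Optional[NoiseSettings] = NoiseSettings()
    intensity_jitter: float = 0.05


class ReconstructSettings(_Strict):
    z_um: Optional[float] = None
    autofocus_z_min_um: Optional[float] = None
    autofocus_z_max_um: Optional[float] = None
    n_iter: int = 20
    constraint: Literal["absorption", "positive_phase", "real", "none"] = "absorption"

    @model_validator(mode="after")
    def _check_z(self) -> "ReconstructSettings":
        has_range = (self.autofocus_z_min_um is not None
                     and self.autofocus_z_max_um is not None)
        if self.z_um is None and not has_range:
            raise ValueError(
                "reconstruction needs either z_um or an autofocus range "
                "(autofocus_z_min_um and autofocus_z_max_um)"
            )
        return self


class MetrologySettings(_Strict):
    line_start: tuple[float, float] = (0.0, 0.0)  # (y, x) px
    line_end: tuple[float, float] = (0.0, 0.0)
    n_lines: int = 20
    spacing_px: float = 1.0


class DetectSettings(_Strict):
    radius_min_um: float = 2.0
    radius_max_um: float = 5.0
    sensitivity: float = 0.45
    border_px: int = 16
    chamber_depth_um: Optional[float] = None  # required for concentration


class RunConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected."""

    optical: OpticalSettings = OpticalSettings()
    plan: PlanSettings = PlanSettings()
    simulate: SimulateSettings = SimulateSettings()
    reconstruct: Optional[ReconstructSettings] = None
    metrology: MetrologySettings = MetrologySettings()
    detect: DetectSettings = DetectSettings()
    seed: int = 0
    output_dir: str = "holoscope_out"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
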