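"""Run configuration: validated schema and YAML/JSON loading.

A ``RunConfig`` fully describes a simulation run (array, excitation,
medium, phantom, imaging mode, beamforming, Doppler).  Validation happens
before any compute, and error messages name the offending field.  Units
in config files are meters/Hz/seconds (suffixes ``_m``, ``_hz`` make
this explicit); millimeter convenience is not provided to avoid silent
unit mistakes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .geometry import Excitation, Medium, build_linear_array
from .phantoms import (
    PointTarget,
    ScattererField,
    SphereFeature,
    VesselFlowConfig,
    cyst_phantom,
    default_cyst_features,
    image_template_phantom,
    vessel_flow_phantom,
)

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ArrayConfig(_Model):
    n_elements: int = Field(ge=1)
    width_m: float = Field(gt=0)
    height_m: float = Field(gt=0)
    kerf_m: float = Field(ge=0)

    def build(self):
        return build_linear_array(
            self.n_elements, self.width_m, self.height_m, self.kerf_m
        )


class ExcitationConfig(_Model):
    f0_hz: float = Field(gt=0)
    n_cycles: float = Field(default=1.0, gt=0)
    rx_n_cycles: Optional[float] = Field(default=None, gt=0)

    def build_tx(self) -> Excitation:
        return Excitation(f0=self.f0_hz, n_cycles=self.n_cycles)

    def build_rx(self) -> Excitation:
        n = self.rx_n_cycles if self.rx_n_cycles is not None else self.n_cycles
        return Excitation(f0=self.f0_hz, n_cycles=n)


class MediumConfig(_Model):
    c_m_s: float = Field(default=1540.0, gt=0)
    rho_kg_m3: float = Field(default=1000.0, gt=0)

    def build(self) -> Medium:
        return Medium(sound_speed=self.c_m_s, density=self.rho_kg_m3)


class SphereConfig(_Model):
    center_m: tuple[float, float, float]
    radius_m: float = Field(gt=0)
    kind: Literal["anechoic", "hyperechoic"]


class PointConfig(_Model):
    position_m: tuple[float, float, float]
    amplitude: float = 20.0


class PhantomConfig(_Model):
    type: Literal["cyst", "template", "vessel"] = "cyst"
    n_scatterers: int = Field(default=100_000, ge=1)
    region_m: tuple[
        tuple[float, float], tuple[float, float], tuple[float, float]
    ] = ((-0.025, 0.025), (-0.005, 0.005), (0.030, 0.090))
    # cyst phantom
    spheres: list[SphereConfig] = []
    points: list[PointConfig] = []
    default_features: bool = True
    # template phantom
    template_path: Optional[str] = None
    max_weight: float = 1.0e6
    # vessel phantom
    n_static: int = Field(default=50_000, ge=0)
    vessel_radius_m: float = Field(default=0.005, gt=0)
    vessel_angle_deg: float = Field(default=45.0, gt=0, lt=90)
    vessel_center_m: tuple[float, float, float] = (0.0, 0.0, 0.040)
    flow_profile: Literal["laminar", "parabolic"] = "laminar"
    peak_speed_m_s: float = Field(default=0.5, gt=0)
    static_std: float = 25.0

    def build(self, seed: int, scale: float = 1.0):
        n = max(1, int(round(self.n_scatterers * scale)))
        if self.type == "cyst":
            feats: list = [
                SphereFeature(s.center_m, s.radius_m, s.kind) for s in self.spheres
            ] + [PointTarget(p.position_m, p.amplitude) for p in self.points]
            if self.default_features and not feats:
                feats = default_cyst_features()
            return cyst_phantom(self.region_m, n, feats, seed)
        if self.type == "template":
            if self.template_path is None:
                raise ValueError("template phantom requires template_path")
            import imageio.v3 as iio

            img = np.asarray(iio.imread(self.template_path), dtype=float)
            if img.ndim == 3:
                img = img.mean(axis=2)
            return image_template_phantom(
                img, self.region_m, n, seed, self.max_weight
            )
        vcfg = VesselFlowConfig(
            n_moving=n,
            n_static=max(0, int(round(self.n_static * scale))),
            radius=self.vessel_radius_m,
            angle_deg=self.vessel_angle_deg,
            center=self.vessel_center_m,
            static_region=self.region_m,
            profile=self.flow_profile,
            peak_speed=self.peak_speed_m_s,
            static_std=self.static_std,
        )
        return vessel_flow_phantom(vcfg, seed)


class BeamformingConfig(_Model):
    x_m: tuple[float, float, float] = (-0.0224, 0.0224, 0.000175)  # lo, hi, step
    z_m: tuple[float, float, float] = (0.030, 0.090, 0.001)
    f_number: float = Field(default=2.0, gt=0)
    dynamic_range_db: float = Field(default=60.0, gt=0)

    @field_validator("x_m", "z_m")
    @classmethod
    def _step_positive(cls, v):
        if v[2] <= 0 or v[1] <= v[0]:
            raise ValueError("range must be (lo, hi, step) with hi > lo, step > 0")
        return v


class BModeConfig(_Model):
    n_subaperture: int = Field(default=64, ge=1)
    focus_depth_m: float = Field(default=0.060, gt=0)
    receive_foci_m: Optional[list[float]] = None


class PlaneWaveConfig(_Model):
    angles_deg: list[float] = [-6.0, -3.0, 0.0, 3.0, 6.0]


class DopplerConfig(_Model):
    fprf_hz: float = Field(default=5000.0, gt=0)
    frames_per_angle: int = Field(default=10, ge=2)
    cutoff_db: float = Field(default=4.0, ge=0)
    smooth_height_m: float = Field(default=0.00154, gt=0)
    smooth_width_m: float = Field(default=0.00157, gt=0)


class RunConfig(_Model):
    """Validated top-level run description (see module docstring)."""

    mode: Literal["sa", "bmode", "pw", "doppler", "convergence"]
    seed: int = 0
    fs_hz: float = Field(default=16.0e6, gt=0)
    array: ArrayConfig = ArrayConfig(
        n_elements=128, width_m=0.3e-3, height_m=7.0e-3, kerf_m=0.05e-3
    )
    excitation: ExcitationConfig = ExcitationConfig(f0_hz=3.0e6)
    medium: MediumConfig = MediumConfig()
    phantom: PhantomConfig = PhantomConfig()
    beamforming: BeamformingConfig = BeamformingConfig()
    bmode: BModeConfig = BModeConfig()
    plane_wave: PlaneWaveConfig = PlaneWaveConfig()
    doppler: DopplerConfig = DopplerConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the validated config (provenance logging)."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
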