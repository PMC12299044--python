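"""Seeded scatterer phantom generators.

Three media are provided: a cyst/point-target phantom (speckle background
with anechoic and hyperechoic spheres and bright point targets), an
image-template phantom (scatterer amplitude variance shaped by a
grayscale image), and a vessel flow phantom (moving scatterers in a
tilted cylinder over a static speckle background) for color Doppler.

All randomness flows through one `numpy.random.default_rng(seed)` stream
per phantom, with a fixed draw order (positions axis by axis, then
amplitudes), so fields are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ScattererField",
    "SphereFeature",
    "PointTarget",
    "FlowPhantom",
    "VesselFlowConfig",
    "cyst_phantom",
    "image_template_phantom",
    "vessel_flow_phantom",
    "advance_flow",
    "default_cyst_features",
]


@dataclass(frozen=True)
class ScattererField:
    """Point scatterers: (N, 3) positions in meters and N amplitudes.

    Amplitudes are zero-mean by construction; their local variance sets
    the echogenicity (speckle brightness) of the region.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.positions.shape[0] != self.amplitudes.shape[0]:
            raise ValueError("positions/amplitudes length mismatch")

    def __len__(self) -> int:
        return len(self.amplitudes)

    def __add__(self, other: "ScattererField") -> "ScattererField":
        return ScattererField(
            positions=np.vstack([self.positions, other.positions]),
            amplitudes=np.concatenate([self.amplitudes, other.amplitudes]),
            seed=self.seed,
        )


@dataclass(frozen=True)
class SphereFeature:
    """Spherical region that rewrites the base amplitude: 'anechoic'
    zeroes it, 'hyperechoic' multiplies it by ``gain``."""

    center: tuple[float, float, float]
    radius: float
    kind: Literal["anechoic", "hyperechoic"]
    gain: float = 10.0


@dataclass(frozen=True)
class PointTarget:
    """Discrete bright reflector appended to the field."""

    position: tuple[float, float, float]
    amplitude: float = 20.0


def _uniform_box(rng: np.random.Generator, n: int, bounds) -> np.ndarray:
    """Uniform positions in an axis-aligned box; one draw per axis, in
    x, y, z order (stable stream order is part of the API)."""
    (x0, x1), (y0, y1), (z0, z1) = bounds
    x = rng.uniform(x0, x1, n)
    y = rng.uniform(y0, y1, n)
    z = rng.uniform(z0, z1, n)
    return np.column_stack([x, y, z])


def default_cyst_features(
    z_values: Sequence[float] = (0.040, 0.050, 0.060, 0.070, 0.080),
    lateral_offset: float = 0.008,
    radius: float = 0.003,
) -> list[SphereFeature | PointTarget]:
    """Five anechoic spheres, five hyperechoic spheres, and five point
    targets, arranged in three depth columns (anechoic left, points
    center, hyperechoic right)."""
    feats: list[SphereFeature | PointTarget] = []
    for z in z_values:
        feats.append(SphereFeature((-lateral_offset, 0.0, z), radius, "anechoic"))
        feats.append(SphereFeature((+lateral_offset, 0.0, z), radius, "hyperechoic"))
        feats.append(PointTarget((0.0, 0.0, z)))
    return feats


def cyst_phantom(
    region,
    n_scatterers: int,
    features: Sequence[SphereFeature | PointTarget] = (),
    seed: int = 0,
) -> ScattererField:
    """Speckle phantom with anechoic/hyperechoic spheres and point targets.

    ``region`` is ((x0,x1),(y0,y1),(z0,z1)) in meters.  Background
    scatterers are uniform in the region with N(0,1) amplitudes; inside
    an anechoic sphere the amplitude is set to 0, inside a hyperechoic
    sphere it is multiplied by the sphere's gain (10 by default); point
    targets are appended with fixed amplitude (20 by default).
    """
    if n_scatterers <= 0:
        raise ValueError("n_scatterers must be positive")
    rng = np.random.default_rng(seed)
    pos = _uniform_box(rng, n_scatterers, region)
    amp = rng.standard_normal(n_scatterers)
    for f in features:
        if isinstance(f, PointTarget):
            continue
        d2 = ((pos - np.asarray(f.center)) ** 2).sum(axis=1)
        inside = d2 <= f.radius**2
        if f.kind == "anechoic":
            amp[inside] = 0.0
        else:
            amp[inside] *= f.gain
    points = [f for f in features if isinstance(f, PointTarget)]
    if points:
        pos = np.vstack([pos] + [np.asarray(p.position)[None, :] for p in points])
        amp = np.concatenate([amp, [p.amplitude for p in points]])
    return ScattererField(positions=pos, amplitudes=amp, seed=seed)


def image_template_phantom(
    image: np.ndarray,
    region,
    n_scatterers: int,
    seed: int = 0,
    max_weight: float = 1.0e6,
) -> ScattererField:
    """Scatterers whose amplitude variance tracks a grayscale image.

    Pixel values (expected 0..255) are divided by 100, exponentiated,
    the global minimum weight subtracted, and the result uniformly
    rescaled to [0, max_weight]; each scatterer's amplitude is its
    nearest pixel's weight times an independent N(0,1) draw.  The image's
    columns map to the region's x extent and its rows to the z extent;
    scatterers falling outside the image bounds are excluded.  A constant
    image degenerates to all-zero weights (valid output).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if n_scatterers <= 0:
        raise ValueError("n_scatterers must be positive")
    w = np.exp(img / 100.0)
    w = w - w.min()
    if w.max() > 0:
        w = w * (max_weight / w.max())
    rng = np.random.default_rng(seed)
    pos = _uniform_box(rng, n_scatterers, region)
    gauss = rng.standard_normal(n_scatterers)
    (x0, x1), _, (z0, z1) = region
    nz, nx = img.shape
    col = np.floor((pos[:, 0] - x0) / (x1 - x0) * nx).astype(int)
    row = np.floor((pos[:, 2] - z0) / (z1 - z0) * nz).astype(int)
    inb = (col >= 0) & (col < nx) & (row >= 0) & (row < nz)
    pos = pos[inb]
    amp = w[row[inb], col[inb]] * gauss[inb]
    return ScattererField(positions=pos, amplitudes=amp, seed=seed)


@dataclass(frozen=True)
class VesselFlowConfig:
    """Geometry and kinematics of the vessel flow phantom.

    The vessel is a cylinder of ``radius`` through ``center`` whose axis
    lies in the imaging (x-z) plane at ``angle_deg`` from the beam (+z)
    axis; ``flow_toward_array`` selects the axial flow sense (toward the
    array gives positive Doppler estimates under this package's sign
    convention).  Moving-scatterer amplitudes are N(0,1); static
    background amplitudes are N(0, static_std^2) in a box excluding the
    vessel (the paper-style tissue background uses static_std = 25,
    i.e. variance 625).
    """

    n_moving: int = 50_000
    n_static: int = 50_000
    radius: float = 0.005
    angle_deg: float = 45.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.040)
    half_length: float = 0.030
    static_region: tuple = ((-0.030, 0.030), (-0.005, 0.005), (0.010, 0.080))
    profile: Literal["laminar", "parabolic"] = "laminar"
    peak_speed: float = 0.5
    static_std: float = 25.0
    flow_toward_array: bool = True


@dataclass(frozen=True)
class FlowPhantom:
    """Moving scatterers (with per-scatterer velocities) inside a tilted
    cylindrical vessel, plus a static background field."""

    moving: ScattererField
    velocities: np.ndarray  # (Nm, 3) m/s
    static: ScattererField
    config: VesselFlowConfig
    # axial coordinate of each mover along the vessel axis (recycling state)
    axial_pos: np.ndarray = field(repr=False, default=None)  # type: ignore

    @property
    def axis_unit(self) -> np.ndarray:
        th = np.radians(self.config.angle_deg)
        return np.array([np.sin(th), 0.0, np.cos(th)])

    @property
    def beam_to_flow_angle_rad(self) -> float:
        """Angle between the beam (+z) and the flow direction, folded to
        [0, pi/2] (the Doppler cos(theta) correction is sign-handled by
        the estimator's output sign)."""
        return float(np.radians(self.config.angle_deg))

    def all_scatterers(self) -> ScattererField:
        return self.moving + self.static

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance of points from the vessel axis."""
        u = self.axis_unit
        w = points - np.asarray(self.config.center)
        along = w @ u
        return np.linalg.norm(w - along[:, None] * u[None, :], axis=1)


def _speed_profile(cfg: VesselFlowConfig, rho: np.ndarray) -> np.ndarray:
    if cfg.profile == "laminar":
        return np.full_like(rho, cfg.peak_speed)
    if cfg.profile == "parabolic":
        return cfg.peak_speed * (1.0 - (rho / cfg.radius) ** 2)
    raise ValueError(f"unknown profile: {cfg.profile}")


def vessel_flow_phantom(config: VesselFlowConfig, seed: int = 0) -> FlowPhantom:
    """Build the vessel flow phantom.

    Movers are uniform in the cylinder (axial uniform, radial by the
    area-uniform sqrt rule); their speeds follow the configured profile
    (laminar: peak everywhere; parabolic: peak*(1 - (rho/R)^2), the
    Poiseuille form).  Static scatterers are uniform in the background
    box with the cylinder carved out by rejection.
    """
    cfg = config
    if cfg.radius <= 0:
        raise ValueError("radius must be positive")
    if not 0.0 < cfg.angle_deg < 90.0:
        raise ValueError("vessel angle must be in (0, 90) degrees for Doppler")
    rng = np.random.default_rng(seed)
    th = np.radians(cfg.angle_deg)
    u = np.array([np.sin(th), 0.0, np.cos(th)])
    # orthonormal frame of the cylinder cross-section
    e1 = np.array([np.cos(th), 0.0, -np.sin(th)])
    e2 = np.array([0.0, 1.0, 0.0])
    s = rng.uniform(-cfg.half_length, cfg.half_length, cfg.n_moving)
    rho = cfg.radius * np.sqrt(rng.uniform(0.0, 1.0, cfg.n_moving))
    phi = rng.uniform(0.0, 2.0 * np.pi, cfg.n_moving)
    center = np.asarray(cfg.center)
    pos = (
        center[None, :]
        + s[:, None] * u[None, :]
        + rho[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    amp = rng.standard_normal(cfg.n_moving)
    speed = _speed_profile(cfg, rho)
    direction = -u if cfg.flow_toward_array else u
    vel = speed[:, None] * direction[None, :]
    moving = ScattererField(positions=pos, amplitudes=amp, seed=seed)

    # static background with the vessel carved out (rejection sampling)
    kept_pos: list[np.ndarray] = []
    n_left = cfg.n_static
    guard = 0
    while n_left > 0:
        cand = _uniform_box(rng, max(n_left * 2, 1024), cfg.static_region)
        w = cand - center
        along = w @ u
        r = np.linalg.norm(w - along[:, None] * u[None, :], axis=1)
        ok = cand[r > cfg.radius]
        kept_pos.append(ok[:n_left])
        n_left -= min(len(ok), n_left)
        guard += 1
        if guard > 200:
            raise ValueError("static region is (almost) entirely inside the vessel")
    spos = np.vstack(kept_pos)
    samp = cfg.static_std * rng.standard_normal(cfg.n_static)
    static = ScattererField(positions=spos, amplitudes=samp, seed=seed)
    return FlowPhantom(
        moving=moving, velocities=vel, static=static, config=cfg, axial_pos=s
    )


def advance_flow(phantom: FlowPhantom, dt: float) -> FlowPhantom:
    """Advance mover positions by velocity * dt; movers leaving the
    cylinder's axial extent re-enter at the opposite end with the same
    radial offset and speed (wrap-around preserves uniform density).
    Static scatterers are untouched."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    cfg = phantom.config
    u = phantom.axis_unit
    # signed axial displacement along +u
    ds = (phantom.velocities @ u) * dt
    s_new = phantom.axial_pos + ds
    span = 2.0 * cfg.half_length
    wrapped = np.mod(s_new + cfg.half_length, span) - cfg.half_length
    pos = phantom.moving.positions + (wrapped - phantom.axial_pos)[:, None] * u[None, :]
    moving = ScattererField(
        positions=pos, amplitudes=phantom.moving.amplitudes,
        seed=phantom.moving.seed,
    )
    return FlowPhantom(
        moving=moving, velocities=phantom.velocities, static=phantom.static,
        config=cfg, axial_pos=wrapped,
    )
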