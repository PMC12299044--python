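"""End-to-end color Doppler simulation driver.

Acquisition model: for each plane-wave steering angle, ``frames_per_angle``
successive acquisitions are fired at the pulse repetition frequency while
the flow phantom advances between pulses; the static background is
frame-invariant, so its RF is computed once per angle and superposed on
each moving-scatterer frame (exact, by linearity).  Every acquisition is
beamformed onto a common grid, demodulated, wall-filtered per angle, and
the per-angle lag-one autocorrelations are complex-averaged across angles
before the Kasai phase read-out.  A 4 dB magnitude threshold (relative to
the post-wall-filter peak) gates the estimates, and a Hamming moving
average smooths the velocity map.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .beamforming import BeamformedFrame, BeamformingGrid, das_beamform
from .doppler import (
    DopplerEnsemble,
    VelocityMap,
    ensemble_from_frames,
    lag1_autocorrelation,
    magnitude_threshold,
    spatial_smooth,
    velocity_from_lag1,
    wall_filter,
)
from .geometry import Excitation, Medium, TimeGrid, TransducerArray, build_linear_array
from .phantoms import FlowPhantom, VesselFlowConfig, advance_flow, vessel_flow_phantom
from .rf import auto_time_grid, simulate_plane_wave

__all__ = [
    "ColorDopplerConfig",
    "ColorDopplerResult",
    "simulate_color_doppler",
    "vessel_pixel_mask",
    "vessel_slab_mask",
]


@dataclass(frozen=True)
class ColorDopplerConfig:
    """Full parameterization of a plane-wave color Doppler run.

    Defaults follow the carotid-style reference scenario: a 256-element
    0.35 mm-pitch array, 2.5 MHz four-cycle transmit / one-cycle receive
    waveforms, fs 20 MHz, five steering angles in [-6, +6] degrees with
    ten acquisitions each at fPRF 5 kHz, f-number 1.5, a 4 dB magnitude
    cutoff and a 1.54 x 1.57 mm Hamming smoothing window.
    """

    n_elements: int = 256
    width: float = 0.3e-3
    height: float = 7.0e-3
    kerf: float = 0.05e-3
    f0: float = 2.5e6
    tx_cycles: float = 4.0
    rx_cycles: float = 1.0
    fs: float = 20.0e6
    sound_speed: float = 1540.0
    density: float = 1000.0
    angles_deg: tuple[float, ...] = (-6.0, -3.0, 0.0, 3.0, 6.0)
    frames_per_angle: int = 10
    fprf: float = 5.0e3
    vessel: VesselFlowConfig = field(default_factory=VesselFlowConfig)
    grid_x: tuple[float, float, float] = (-0.015, 0.015, 0.35e-3)  # lo, hi, step
    grid_z: tuple[float, float, float] = (0.025, 0.055, 0.5e-3)
    f_number: float = 1.5
    cutoff_db: float = 4.0
    smooth_height: float = 1.54e-3
    smooth_width: float = 1.57e-3
    seed: int = 0

    def build_array(self) -> TransducerArray:
        return build_linear_array(self.n_elements, self.width, self.height, self.kerf)

    def build_grid(self) -> BeamformingGrid:
        x0, x1, dx = self.grid_x
        z0, z1, dz = self.grid_z
        return BeamformingGrid(
            x=np.arange(x0, x1 + dx / 2, dx),
            z=np.arange(z0, z1 + dz / 2, dz),
            f_number=self.f_number,
        )


@dataclass
class ColorDopplerResult:
    """Velocity maps and intermediates of one color Doppler run."""

    velocity: VelocityMap          # smoothed, angle-corrected (m/s)
    velocity_raw: VelocityMap      # pre-smoothing
    mask: np.ndarray               # magnitude-threshold gate
    grid: BeamformingGrid
    phantom: FlowPhantom
    config: ColorDopplerConfig
    bmode_frame: BeamformedFrame | None = None  # compounded first acquisition


def vessel_pixel_mask(grid: BeamformingGrid, phantom: FlowPhantom,
                      dilate: float = 0.0) -> np.ndarray:
    """Pixels whose (x, 0, z) position lies within ``dilate`` meters of
    the vessel interior (dilate=0: strictly inside)."""
    X, Z = np.meshgrid(grid.x, grid.z)
    pts = np.column_stack([X.ravel(), np.zeros(X.size), Z.ravel()])
    rho = phantom.radial_distance(pts).reshape(X.shape)
    return rho <= phantom.config.radius + dilate


def vessel_slab_mask(grid: BeamformingGrid, phantom: FlowPhantom,
                     half_height: float = 1.5e-3) -> np.ndarray:
    """Thin axial slab through the vessel-center depth, intersected with
    the vessel interior.

    For a vessel tilted 45 degrees in the imaging plane, every full-depth
    A-line chord samples the complete radial range, so depth-averaging
    over the whole interior flattens any radial flow profile; within this
    slab, lateral position maps (up to the slab thickness) to radial
    distance, so the lateral average recovers the cross-sectional
    profile.
    """
    zc = phantom.config.center[2]
    X, Z = np.meshgrid(grid.x, grid.z)
    slab = np.abs(Z - zc) <= half_height
    return slab & vessel_pixel_mask(grid, phantom)


def _common_time_grid(cfg: ColorDopplerConfig, array, phantom, exc_tx, exc_rx,
                      medium) -> TimeGrid:
    """One lattice-aligned grid covering all angles, both scatterer
    populations, and the full slow-time motion excursion."""
    from .rf import TransmitEvent
    from .geometry import plane_wave_delays

    pts = np.vstack([phantom.moving.positions, phantom.static.positions])
    events = []
    for ang in cfg.angles_deg:
        dv = plane_wave_delays(array, ang, medium)
        events.append(
            TransmitEvent(
                tx_indices=np.arange(array.n_elements), delays=dv,
                apodization=np.ones(array.n_elements), label=f"pw{ang}",
                angle_deg=ang,
            )
        )
    base = auto_time_grid(array, pts, events, exc_tx, exc_rx, medium, cfg.fs)
    # widen for scatterer motion over the whole acquisition sequence
    total_t = cfg.frames_per_angle * len(cfg.angles_deg) / cfg.fprf
    travel = cfg.vessel.peak_speed * total_t
    pad = int(np.ceil(2.0 * travel / cfg.sound_speed * cfg.fs)) + 8
    return TimeGrid(
        fs=cfg.fs,
        t0=base.t0 - pad / cfg.fs,
        n_samples=base.n_samples + 2 * pad,
    )


def simulate_color_doppler(
    cfg: ColorDopplerConfig, keep_bmode: bool = True
) -> ColorDopplerResult:
    """Run the full chain: phantom -> RF -> beamforming -> Doppler map."""
    array = cfg.build_array()
    medium = Medium(sound_speed=cfg.sound_speed, density=cfg.density)
    exc_tx = Excitation(f0=cfg.f0, n_cycles=cfg.tx_cycles)
    exc_rx = Excitation(f0=cfg.f0, n_cycles=cfg.rx_cycles)
    bgrid = cfg.build_grid()
    phantom0 = vessel_flow_phantom(cfg.vessel, seed=cfg.seed)
    tgrid = _common_time_grid(cfg, array, phantom0, exc_tx, exc_rx, medium)

    dt = 1.0 / cfg.fprf
    theta = phantom0.beam_to_flow_angle_rad
    phantom = phantom0
    per_angle_R: list[np.ndarray] = []
    all_filtered: list[np.ndarray] = []
    first_frames: list[BeamformedFrame] = []
    for ang in cfg.angles_deg:
        rf_static = simulate_plane_wave(
            array, phantom0.static, exc_tx, medium, cfg.fs, [ang],
            excitation_rx=exc_rx, grid=tgrid,
        )
        frames = []
        for _ in range(cfg.frames_per_angle):
            rf_mov = simulate_plane_wave(
                array, phantom.moving, exc_tx, medium, cfg.fs, [ang],
                excitation_rx=exc_rx, grid=tgrid,
            )
            bf = das_beamform(rf_mov + rf_static, bgrid, analytic=True)[0]
            frames.append(bf)
            phantom = advance_flow(phantom, dt)
        if keep_bmode:
            first_frames.append(frames[0])
        ens = ensemble_from_frames(frames, cfg.fprf, cfg.f0, theta, medium)
        ens = wall_filter(ens)
        all_filtered.append(ens.frames)
        per_angle_R.append(lag1_autocorrelation(ens))

    combined = DopplerEnsemble(
        frames=np.concatenate(all_filtered, axis=0), fprf=cfg.fprf,
        f0=cfg.f0, angle_rad=theta, medium=medium, grid=bgrid,
    )
    mask = magnitude_threshold(combined, cfg.cutoff_db)
    R = np.mean(per_angle_R, axis=0)
    vraw = velocity_from_lag1(R, cfg.fprf, cfg.f0, theta, medium, bgrid, mask=mask)
    vsm = spatial_smooth(vraw, cfg.smooth_height, cfg.smooth_width)
    bframe = None
    if keep_bmode and first_frames:
        from .beamforming import compound

        bframe = compound(first_frames)
    return ColorDopplerResult(
        velocity=vsm, velocity_raw=vraw, mask=mask, grid=bgrid,
        phantom=phantom0, config=cfg, bmode_frame=bframe,
    )
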