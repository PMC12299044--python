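"""Color Doppler velocity estimation from slow-time ensembles.

The chain follows clinical color-flow processing: beamformed RF frames
are demodulated to complex analytic signals (Hilbert transform along
depth), static tissue is removed by subtracting each pixel's slow-time
mean (the wall filter), low-magnitude pixels are masked, and the mean
inter-pulse phase shift is read off the lag-one slow-time autocorrelation
(the Kasai estimator):

    v = c * fPRF / (4 pi f0 cos(theta)) * atan2(Im R, Re R)

Sign convention: with the analytic signal defined on the depth axis, a
scatterer moving toward the transducer shortens its echo path and
advances the phase, so positive v means flow toward the array.  theta is
the beam-to-flow angle (beam along +z); cos(theta) corrects the axial
velocity component to the along-flow speed, and the estimate is
unambiguous up to the Nyquist speed c*fPRF/(4*f0*cos(theta)).

For multi-angle plane-wave Doppler the ensemble is acquired per steering
angle; lag-one autocorrelations are formed per angle and averaged as
complex numbers before the phase is taken, which keeps inter-angle phase
offsets out of the slow-time statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .beamforming import BeamformedFrame, BeamformingGrid
from .geometry import Medium

__all__ = [
    "DopplerEnsemble",
    "VelocityMap",
    "ensemble_from_frames",
    "wall_filter",
    "magnitude_threshold",
    "lag1_autocorrelation",
    "velocity_from_lag1",
    "autocorrelation_velocity",
    "spatial_smooth",
    "lateral_average_profile",
]


@dataclass
class DopplerEnsemble:
    """K slow-time-ordered complex frames on one beamforming grid."""

    frames: np.ndarray  # (K, nz, nx) complex
    fprf: float
    f0: float
    angle_rad: float
    medium: Medium
    grid: BeamformingGrid

    def __post_init__(self) -> None:
        if self.frames.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if self.fprf <= 0:
            raise ValueError("fPRF must be positive")

    @property
    def K(self) -> int:
        return self.frames.shape[0]

    @property
    def nyquist_velocity(self) -> float:
        return self.medium.sound_speed * self.fprf / (
            4.0 * self.f0 * np.cos(self.angle_rad)
        )


@dataclass
class VelocityMap:
    """Per-pixel angle-corrected flow velocity (m/s, positive toward the
    transducer) with a validity mask and the Nyquist bound."""

    v: np.ndarray
    valid: np.ndarray
    nyquist: float
    grid: BeamformingGrid


def ensemble_from_frames(
    frames: Sequence[BeamformedFrame],
    fprf: float,
    f0: float,
    angle_rad: float,
    medium: Medium,
) -> DopplerEnsemble:
    """Collect beamformed frames into a complex slow-time ensemble.

    Analytic (complex) frames are used as-is — the preferred route, with
    demodulation done along the RF time axis during beamforming.  Real
    frames are demodulated here with a Hilbert transform along depth,
    which is only valid when the axial pixel step is below a quarter
    wavelength."""
    data = np.stack(
        [
            f.data if f.is_analytic else hilbert(f.data, axis=0)
            for f in frames
        ]
    )
    return DopplerEnsemble(
        frames=data, fprf=fprf, f0=f0, angle_rad=angle_rad, medium=medium,
        grid=frames[0].grid,
    )


def wall_filter(ensemble: DopplerEnsemble) -> DopplerEnsemble:
    """Remove static tissue: subtract each pixel's slow-time mean.

    Exactly cancels any frame-invariant (static-scatterer) component by
    linearity; the filtered ensemble has zero slow-time mean everywhere.
    """
    if ensemble.K < 2:
        raise ValueError("wall filter needs at least 2 frames")
    out = ensemble.frames - ensemble.frames.mean(axis=0, keepdims=True)
    return DopplerEnsemble(
        frames=out, fprf=ensemble.fprf, f0=ensemble.f0,
        angle_rad=ensemble.angle_rad, medium=ensemble.medium,
        grid=ensemble.grid,
    )


def magnitude_threshold(
    ensemble: DopplerEnsemble, cutoff_db: float = 4.0
) -> np.ndarray:
    """Mask of pixels whose slow-time mean magnitude reaches within
    ``cutoff_db`` of the peak: mag >= peak * 10^(-cutoff/20).

    After wall filtering, residual signal in low-magnitude regions is
    dominated by numerical/static leftovers with meaningless phase; the
    threshold suppresses those estimates.
    """
    mag = np.abs(ensemble.frames).mean(axis=0)
    peak = mag.max()
    if peak == 0.0:
        return np.zeros(mag.shape, dtype=bool)
    return mag >= peak * 10.0 ** (-cutoff_db / 20.0)


def lag1_autocorrelation(ensemble: DopplerEnsemble) -> np.ndarray:
    """Ensemble-averaged lag-one slow-time autocorrelation:
    R = 1/(K-1) * sum_k conj(s_k) s_{k+1}."""
    s = ensemble.frames
    return (np.conj(s[:-1]) * s[1:]).mean(axis=0)


def velocity_from_lag1(
    R: np.ndarray,
    fprf: float,
    f0: float,
    angle_rad: float,
    medium: Medium,
    grid: BeamformingGrid,
    mask: np.ndarray | None = None,
) -> VelocityMap:
    """Kasai phase-to-velocity mapping of a lag-one autocorrelation."""
    ct = np.cos(angle_rad)
    if abs(ct) < 1e-12:
        raise ValueError("flow perpendicular to the beam: cos(theta) = 0")
    scale = medium.sound_speed * fprf / (4.0 * np.pi * f0 * ct)
    # toward-the-transducer motion advances the analytic-signal phase
    v = scale * np.arctan2(R.imag, R.real)
    valid = np.ones(R.shape, dtype=bool) if mask is None else mask.copy()
    v = np.where(valid, v, 0.0)
    nyq = medium.sound_speed * fprf / (4.0 * f0 * ct)
    return VelocityMap(v=v, valid=valid, nyquist=nyq, grid=grid)


def autocorrelation_velocity(
    ensemble: DopplerEnsemble, mask: np.ndarray | None = None
) -> VelocityMap:
    """Kasai autocorrelation velocity estimate for one (wall-filtered)
    ensemble.  Multi-angle acquisitions should average
    :func:`lag1_autocorrelation` outputs across angles and call
    :func:`velocity_from_lag1` directly."""
    R = lag1_autocorrelation(ensemble)
    return velocity_from_lag1(
        R, ensemble.fprf, ensemble.f0, ensemble.angle_rad, ensemble.medium,
        ensemble.grid, mask=mask,
    )


def _window_px(size_m: float, spacing_m: float) -> int:
    n = max(1, int(round(size_m / spacing_m)))
    return n if n % 2 == 1 else n + 1


def spatial_smooth(
    vmap: VelocityMap, window_height: float, window_width: float
) -> VelocityMap:
    """Separable Hamming-weighted moving average, normalized over the
    valid mask (invalid pixels contribute neither value nor weight).

    ``window_height``/``window_width`` are the axial/lateral window
    extents in meters; they are converted to odd pixel counts using the
    grid spacing.
    """
    g = vmap.grid
    dz = float(np.mean(np.diff(g.z))) if len(g.z) > 1 else window_height
    dx = float(np.mean(np.diff(g.x))) if len(g.x) > 1 else window_width
    nh = _window_px(window_height, dz)
    nw = _window_px(window_width, dx)
    if nh > len(g.z) or nw > len(g.x):
        raise ValueError("smoothing window larger than the grid")
    wz = np.hamming(nh) if nh > 1 else np.ones(1)
    wx = np.hamming(nw) if nw > 1 else np.ones(1)

    def sep_conv(a: np.ndarray) -> np.ndarray:
        from scipy.ndimage import convolve1d

        out = convolve1d(a, wz, axis=0, mode="constant")
        return convolve1d(out, wx, axis=1, mode="constant")

    m = vmap.valid.astype(float)
    num = sep_conv(vmap.v * m)
    den = sep_conv(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    # smoothing interpolates across gated-out pixels: a pixel is valid
    # when any pixel in its window was, which is what turns the sparse
    # thresholded estimates into the filled-in color-flow map
    return VelocityMap(v=sm, valid=den > 0, nyquist=vmap.nyquist,
                       grid=vmap.grid)


def lateral_average_profile(
    vmap: VelocityMap, region: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-A-line mean velocity over a region of interest.

    ``region`` is a boolean (nz, nx) mask; for each lateral position the
    velocity is averaged over the region's (valid) depth samples.
    Returns ``(x, raw, normalized)`` where ``normalized`` divides by the
    profile value at the lateral position nearest x = 0.  Columns with no
    contributing pixel are NaN.

    Note on tilted vessels: averaging over a vessel's *full* axial
    intersection returns the cross-sectional mean at every lateral
    position (a 45-degree cylinder's vertical chords all sample the whole
    radial range), flattening any radial profile; to resolve the profile,
    pass a thin axial slab through the vessel center so that lateral
    position maps to radial distance (see docs/methods.md).
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != vmap.v.shape:
        raise ValueError("region mask shape mismatch")
    sel = region & vmap.valid
    if not sel.any():
        raise ValueError("empty region")
    cnt = sel.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(cnt > 0, (vmap.v * sel).sum(axis=0) / np.maximum(cnt, 1),
                       np.nan)
    i0 = int(np.argmin(np.abs(vmap.grid.x)))
    ref = raw[i0]
    if not np.isfinite(ref) or ref == 0.0:
        raise ValueError("profile reference at x=0 is empty or zero")
    return vmap.grid.x.copy(), raw, raw / ref
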