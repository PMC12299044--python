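"""Accuracy metrics and the sampling-frequency convergence harness.

NRMSE is the root-mean-square error of a test RF dataset against a
reference, normalized by the reference RMS, evaluated only over the
echo-containing samples (reference envelope above a small fraction of
its peak).  The convergence harness compares the three delay-handling
paths (analytic re-evaluation, cached linear-interpolation shifting,
cached 4x-upsampled shifting) at several sampling frequencies against a
single high-fs dense-aperture reference, mirroring how transient-field
codes are conventionally validated against an asymptotically exact
discretization.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .field import element_quadrature, uniform_quadrature
from .geometry import Excitation, Medium, build_linear_array
from .phantoms import ScattererField
from .rf import RFDataSet, simulate_plane_wave

__all__ = [
    "nrmse",
    "ConvergenceConfig",
    "ConvergenceReport",
    "convergence_study",
    "PSFMetrics",
    "psf_metrics",
    "fit_parabolic_profile",
]

def _resample_to(test_trace, test_grid, ref_grid) -> np.ndarray:
    """Linear resample of one trace onto the reference time axis (zero
    outside the test support)."""
    return np.interp(
        ref_grid.times, test_grid.times, test_trace, left=0.0, right=0.0
    )

def nrmse(
    test: RFDataSet,
    reference: RFDataSet,
    envelope_threshold: float = 1.0e-3,
) -> float:
    """NRMSE of ``test`` against ``reference`` over echo-containing samples.

    Test traces are linearly resampled onto the reference grid.  The
    evaluation window keeps samples where the reference trace envelope
    exceeds ``envelope_threshold`` times the dataset's peak envelope;
    RMS(test - ref) / RMS(ref) is accumulated over all events and
    channels jointly.
    """
    if len(test) != len(reference):
        raise ValueError("event count mismatch")
    num = 0.0
    den = 0.0
    n_win = 0
    for t_ev, r_ev in zip(test.data, reference.data):
        env = np.abs(hilbert(r_ev, axis=-1))
        peak = env.max()
        if peak == 0.0:
            raise ValueError("reference is zero")
        win = env > envelope_threshold * peak
        n_win += int(win.sum())
        for j in range(r_ev.shape[0]):
            w = win[j]
            if not w.any():
                continue
            r = r_ev[j]
            t = _resample_to(t_ev[j], test.grid, reference.grid)
            num += float(((t - r)[w] ** 2).sum())
            den += float((r[w] ** 2).sum())
    if n_win == 0 or den == 0.0:
        raise ValueError("no echo-containing samples in the reference window")
    return float(np.sqrt(num / den))

@dataclass(frozen=True)
class ConvergenceConfig:
    """Desk-scale plane-wave convergence study setup.

    The reference is the analytic-delay path evaluated at
    ``ref_fs_factor`` times the largest test fs with a dense uniform
    aperture discretization at ``dense_spacing_wavelengths`` of the
    excitation wavelength (asymptotically exact in both time and
    aperture sampling).
    """

    n_elements: int = 16
    width: float = 0.3e-3
    height: float = 7.0e-3
    kerf: float = 0.05e-3
    f0: float = 3.0e6
    n_cycles: float = 1.0
    sound_speed: float = 1540.0
    density: float = 1000.0
    angles_deg: tuple[float, ...] = (-6.0, 0.0, 6.0)
    n_scatterers: int = 50
    region: tuple = ((-5e-3, 5e-3), (-1e-3, 1e-3), (0.025, 0.035))
    seed: int = 0
    fs_list: tuple[float, ...] = (12e6, 24e6, 48e6, 96e6)
    ref_fs_factor: int = 16
    quad_order: tuple[int, int] = (1, 6)
    dense_spacing_wavelengths: float = 0.125
    methods: tuple[str, ...] = ("analytic", "cached_linear", "cached_upsampled")

@dataclass
class ConvergenceReport:
    """Rows of (method, fs, NRMSE, wall seconds) plus the reference
    descriptor.  Wall time is informational only."""

    rows: list[dict] = field(default_factory=list)
    reference: str = ""

    def nrmse_of(self, method: str) -> tuple[np.ndarray, np.ndarray]:
        sel = sorted(
            (r for r in self.rows if r["method"] == method),
            key=lambda r: r["fs"],
        )
        return (
            np.array([r["fs"] for r in sel]),
            np.array([r["nrmse"] for r in sel]),
        )

    def to_csv(self, path) -> None:
        lines = ["method,fs_hz,nrmse,seconds"]
        for r in self.rows:
            lines.append(
                f"{r['method']},{r['fs']:.6g},{r['nrmse']:.8g},{r['seconds']:.4g}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

def convergence_study(config: ConvergenceConfig | None = None) -> ConvergenceReport:
    """Run the delay-mode x sampling-frequency convergence comparison."""
    cfg = config or ConvergenceConfig()
    array = build_linear_array(cfg.n_elements, cfg.width, cfg.height, cfg.kerf)
    exc = Excitation(f0=cfg.f0, n_cycles=cfg.n_cycles)
    medium = Medium(sound_speed=cfg.sound_speed, density=cfg.density)
    rng = np.random.default_rng(cfg.seed)
    (x0, x1), (y0, y1), (z0, z1) = cfg.region
    pos = np.column_stack(
        [
            rng.uniform(x0, x1, cfg.n_scatterers),
            rng.uniform(y0, y1, cfg.n_scatterers),
            rng.uniform(z0, z1, cfg.n_scatterers),
        ]
    )
    amps = rng.standard_normal(cfg.n_scatterers)
    scat = ScattererField(positions=pos, amplitudes=amps, seed=cfg.seed)
    lam = cfg.sound_speed / cfg.f0
    dense = uniform_quadrature(array, cfg.dense_spacing_wavelengths * lam)
    ref_fs = cfg.ref_fs_factor * max(cfg.fs_list)
    reference = simulate_plane_wave(
        array, scat, exc, medium, ref_fs, cfg.angles_deg, quad=dense,
        delay_mode="analytic",
    )
    quad = element_quadrature(array, *cfg.quad_order)
    report = ConvergenceReport(
        reference=(
            f"analytic delays, fs={ref_fs:.4g} Hz, uniform "
            f"{cfg.dense_spacing_wavelengths:g} lambda aperture sampling"
        )
    )
    for method in cfg.methods:
        for fs in cfg.fs_list:
            t0 = time.perf_counter()
            test = simulate_plane_wave(
                array, scat, exc, medium, fs, cfg.angles_deg, quad=quad,
                delay_mode=method,
            )
            dtb = time.perf_counter() - t0
            report.rows.append(
                {
                    "method": method,
                    "fs": fs,
                    "nrmse": nrmse(test, reference),
                    "seconds": dtb,
                }
            )
    return report

@dataclass(frozen=True)
class PSFMetrics:
    """Point-spread-function summary measured on a B-mode image."""

    peak_x: float
    peak_z: float
    position_error: float
    lateral_width_6db: float
    axial_width_6db: float

def _width_6db(axis: np.ndarray, profile_db: np.ndarray, peak_idx: int) -> float:
    """-6 dB full width around ``peak_idx`` with linear-interpolated
    crossings (NaN if a crossing runs off the grid)."""
    level = profile_db[peak_idx] - 6.0
    lo = np.nan
    for i in range(peak_idx, 0, -1):
        if profile_db[i - 1] < level <= profile_db[i]:
            f = (profile_db[i] - level) / (profile_db[i] - profile_db[i - 1])
            lo = axis[i] - f * (axis[i] - axis[i - 1])
            break
    hi = np.nan
    for i in range(peak_idx, len(axis) - 1):
        if profile_db[i + 1] < level <= profile_db[i]:
            f = (profile_db[i] - level) / (profile_db[i] - profile_db[i + 1])
            hi = axis[i] + f * (axis[i + 1] - axis[i])
            break
    return float(hi - lo)

def psf_metrics(image, true_position) -> PSFMetrics:
    """Locate the image peak and measure -6 dB widths along the lateral
    and axial cuts through it.

    ``true_position`` is (x, z) in meters; ``position_error`` is the
    Euclidean distance from the peak pixel to it.  A peak on the image
    border (or a featureless image) is rejected.
    """
    db = image.db
    if db.max() == db.min():
        raise ValueError("featureless image: no dominant target")
    iz, ix = np.unravel_index(np.argmax(db), db.shape)
    if iz in (0, db.shape[0] - 1) or ix in (0, db.shape[1] - 1):
        raise ValueError("peak on the image border")
    gx, gz = image.grid.x, image.grid.z
    x0, z0 = float(true_position[0]), float(true_position[1])
    err = float(np.hypot(gx[ix] - x0, gz[iz] - z0))
    return PSFMetrics(
        peak_x=float(gx[ix]),
        peak_z=float(gz[iz]),
        position_error=err,
        lateral_width_6db=_width_6db(gx, db[iz, :], ix),
        axial_width_6db=_width_6db(gz, db[:, ix], iz),
    )

def fit_parabolic_profile(
    x: np.ndarray, v: np.ndarray, x_max: float
) -> tuple[float, float, float]:
    """Least-squares fit of v(x) = v0 * (1 - (x/R)^2) over |x| <= x_max.

    Returns (v0, R, r_squared); only finite samples participate.
    """
    sel = np.isfinite(v) & (np.abs(x) <= x_max)
    if sel.sum() < 3:
        raise ValueError("not enough samples for a parabolic fit")
    xs, vs = x[sel], v[sel]
    A = np.column_stack([np.ones_like(xs), xs**2])
    coef, *_ = np.linalg.lstsq(A, vs, rcond=None)
    a, b = coef
    pred = A @ coef
    ss_res = float(((vs - pred) ** 2).sum())
    ss_tot = float(((vs - vs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if b >= 0 or a <= 0:
        return float(a), float("nan"), r2
    return float(a), float(np.sqrt(-a / b)), r2
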