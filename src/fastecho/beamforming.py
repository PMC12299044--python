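"""Delay-and-sum beamforming, envelope detection, log compression, and
coherent compounding.

Receive focusing is dynamic by default: at each focal point (x, z) every
channel j inside the constant-f-number cone |x_j - x| <= z / (2 f#) is
sampled (linear interpolation) at the two-way time

    t(x, z; j) = t_tx(x, z) + |r_f - r_j| / c

with the transmit time depending on the imaging mode: the element
time-of-flight for synthetic aperture, the steered wavefront arrival
(z cos(theta) + x sin(theta))/c plus the event's stored delay offset for
plane waves, and the sub-aperture-center time-of-flight for B-mode.  A
fixed-foci receive variant (segment-wise frozen focal laws) reproduces
conventional multi-zone B-mode receive focusing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .geometry import Medium, TimeGrid
from .rf import RFDataSet, TransmitEvent

__all__ = [
    "BeamformingGrid",
    "BeamformedFrame",
    "BModeImage",
    "das_beamform",
    "envelope_logcompress",
    "compound",
    "bmode_image",
]


@dataclass(frozen=True)
class BeamformingGrid:
    """Lateral (x) and axial (z) focal positions plus the receive f-number."""

    x: np.ndarray
    z: np.ndarray
    f_number: float = 2.0

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if np.any(z <= 0) or np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing and positive")
        if self.f_number <= 0:
            raise ValueError("f-number must be positive")
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "z", z)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.z), len(self.x))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BeamformingGrid)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.z, other.z)
            and self.f_number == other.f_number
        )


@dataclass
class BeamformedFrame:
    """Beamformed samples on the (z, x) grid for one transmit event.

    ``data`` is real when the RF traces were beamformed directly and
    complex when the analytic (time-demodulated) traces were beamformed.
    ``valid`` flags pixels whose receive aperture was non-empty.
    """

    data: np.ndarray
    grid: BeamformingGrid
    label: str = ""
    valid: np.ndarray | None = None

    @property
    def is_analytic(self) -> bool:
        return np.iscomplexobj(self.data)


@dataclass
class BModeImage:
    """Log-compressed envelope image: 0 dB at the global peak, clipped at
    -dynamic_range dB."""

    db: np.ndarray
    grid: BeamformingGrid
    dynamic_range: float


def _sample_traces(trace: np.ndarray, tau: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Linearly interpolate one channel trace at times ``tau`` (0 outside)."""
    pos = (tau - grid.t0) * grid.fs
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    ok = (i0 >= 0) & (i0 < len(trace) - 1)
    i0c = np.clip(i0, 0, len(trace) - 2)
    out = (1.0 - frac) * trace[i0c] + frac * trace[i0c + 1]
    out[~ok] = 0.0
    return out


def _transmit_time(ev: TransmitEvent, X: np.ndarray, Z: np.ndarray,
                   rf: RFDataSet, c: float) -> np.ndarray:
    if ev.angle_deg is not None:  # plane wave
        th = np.radians(ev.angle_deg)
        return (Z * np.cos(th) + X * np.sin(th)) / c + ev.delays.offset
    if ev.ref_position is not None:  # focused sub-aperture (B-mode)
        r = ev.ref_position
        return np.sqrt((X - r[0]) ** 2 + r[1] ** 2 + (Z - r[2]) ** 2) / c
    # synthetic aperture: single transmitting element
    r = rf.array.positions[ev.tx_indices[0]]
    return (
        np.sqrt((X - r[0]) ** 2 + r[1] ** 2 + (Z - r[2]) ** 2) / c
        + ev.delays.offset
    )


def das_beamform(
    rf: RFDataSet,
    grid: BeamformingGrid,
    medium: Medium | None = None,
    receive_foci: Sequence[float] | None = None,
    columns: np.ndarray | None = None,
    analytic: bool = False,
) -> list[BeamformedFrame]:
    """Delay-and-sum beamform every event of ``rf`` onto ``grid``.

    ``analytic``: beamform the analytic RF (Hilbert transform along the
    well-sampled *time* axis before delay-and-sum), yielding complex
    frames whose per-pixel phase is meaningful at any axial pixel
    spacing.  This is the demodulation route used for Doppler (and for
    envelope images on coarse grids): the beamformed A-line carrier has
    an axial period of half a wavelength, so demodulating along the
    depth axis instead would require axial pixel steps below a quarter
    wavelength to avoid aliasing.
    ``receive_foci``: optional fixed receive focal depths; each depth's
    focal law is frozen across its axial segment (nearest-focus
    assignment), instead of the default per-depth dynamic focusing.
    ``columns``: optional index subset of grid.x to beamform (other
    columns stay zero and are flagged invalid) — used by the B-mode
    driver, where each event owns one A-line.
    """
    medium = medium or rf.medium
    c = medium.sound_speed
    nz, nx = grid.shape
    cols = np.arange(nx) if columns is None else np.atleast_1d(columns)
    X, Z = np.meshgrid(grid.x[cols], grid.z)
    foci = None if receive_foci is None else np.asarray(receive_foci, float)
    frames = []
    dtype = complex if analytic else float
    # the two-way pulse envelope peaks half the combined burst length
    # after the geometric arrival; compensate so targets map to their
    # true depth
    t_pulse = 0.5 * (rf.excitation_tx.duration + rf.excitation_rx.duration)
    for ev, traces in zip(rf.events, rf.data):
        if analytic:
            traces = hilbert(traces, axis=-1)
        t_tx = _transmit_time(ev, X, Z, rf, c) + t_pulse
        acc = np.zeros(X.shape, dtype=dtype)
        count = np.zeros_like(X, dtype=np.int64)
        rx_set = ev.tx_indices if rf.mode == "bmode" else range(rf.array.n_elements)
        if foci is not None:
            zf = foci[np.argmin(np.abs(grid.z[:, None] - foci[None, :]), axis=1)]
            zf = zf[:, None] * np.ones_like(X)
        for j in rx_set:
            xj = rf.array.centers_x[j]
            ap = np.abs(xj - X) <= Z / (2.0 * grid.f_number)
            if not ap.any():
                continue
            if foci is None:
                t_rx = np.sqrt((X - xj) ** 2 + Z**2) / c
            else:
                t_rx = (np.sqrt((X - xj) ** 2 + zf**2) + (Z - zf)) / c
            s = _sample_traces(traces[j], (t_tx + t_rx)[ap], rf.grid)
            acc[ap] += s
            count[ap] += 1
        data = np.zeros((nz, nx), dtype=dtype)
        valid = np.zeros((nz, nx), dtype=bool)
        data[:, cols] = acc
        valid[:, cols] = count > 0
        frames.append(BeamformedFrame(data=data, grid=grid, label=ev.label,
                                      valid=valid))
    return frames


def envelope_logcompress(
    frame: BeamformedFrame, dynamic_range: float = 60.0
) -> BModeImage:
    """Envelope per A-line, global peak normalization, 20 log10, clipped
    at -dynamic_range dB.

    Real frames are demodulated with a Hilbert transform along depth
    (requires axial pixel steps below a quarter wavelength); analytic
    frames already carry the envelope as their magnitude."""
    if frame.is_analytic:
        env = np.abs(frame.data)
    else:
        env = np.abs(hilbert(frame.data, axis=0))
    peak = env.max()
    if peak == 0.0:
        raise ValueError("all-zero frame: normalization undefined")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    return BModeImage(
        db=np.clip(db, -dynamic_range, 0.0), grid=frame.grid,
        dynamic_range=dynamic_range,
    )


def compound(frames: Sequence[BeamformedFrame]) -> BeamformedFrame:
    """Coherent (pre-envelope) sum of beamformed frames on one grid."""
    if len(frames) == 0:
        raise ValueError("nothing to compound")
    g = frames[0].grid
    for f in frames[1:]:
        if f.grid != g:
            raise ValueError("grid mismatch between frames")
    data = np.sum([f.data for f in frames], axis=0)
    valid = None
    if all(f.valid is not None for f in frames):
        valid = np.any([f.valid for f in frames], axis=0)
    return BeamformedFrame(
        data=data, grid=g, label="+".join(f.label for f in frames), valid=valid
    )


def bmode_image(
    rf: RFDataSet,
    grid: BeamformingGrid,
    dynamic_range: float = 60.0,
    receive_foci: Sequence[float] | None = None,
) -> BModeImage:
    """Assemble a B-mode image: each event is beamformed on its own
    A-line column (nearest grid column), the columns are combined, then
    envelope-detected and log-compressed."""
    frames = []
    for k, ev in enumerate(rf.events):
        col = int(np.argmin(np.abs(grid.x - ev.aline_x)))
        sub = RFDataSet(
            events=[ev], data=[rf.data[k]], grid=rf.grid, array=rf.array,
            medium=rf.medium, excitation_tx=rf.excitation_tx,
            excitation_rx=rf.excitation_rx, mode=rf.mode,
        )
        frames.extend(
            das_beamform(sub, grid, receive_foci=receive_foci,
                         columns=np.array([col]))
        )
    return envelope_logcompress(compound(frames), dynamic_range)
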