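"""Array geometry, excitation waveforms, media, time axes, and delay laws.

Coordinate convention: x is lateral, y is elevation, z is depth. The array
lies in the z=0 plane, centered on the origin, with every element normal
along +z. All quantities are SI internally (meters, seconds, Hz, Pa);
steering angles cross the API boundary in degrees and are converted to
radians immediately.

Delay convention: a transmit delay tau >= 0 means the element fires later,
so its radiated field is p(t - tau). Negative delays are allowed (the RF
data then simply starts earlier); helpers that offset delay vectors to be
non-negative record the offset so downstream beamforming stays consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Medium",
    "Excitation",
    "TimeGrid",
    "TransducerArray",
    "DelayVector",
    "build_linear_array",
    "aline_lateral_positions",
    "plane_wave_delays",
    "focus_delays",
]


class InvalidGeometryError(ValueError):
    """Raised for non-physical array or focus geometry."""


@dataclass(frozen=True)
class Medium:
    """Homogeneous, isotropic, non-dissipative propagation medium.

    Attributes
    ----------
    sound_speed : float
        Speed of sound c in m/s.
    density : float
        Ambient density rho0 in kg/m^3.
    """

    sound_speed: float = 1540.0
    density: float = 1000.0

    def __post_init__(self) -> None:
        if self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("sound_speed and density must be positive")


@dataclass(frozen=True)
class Excitation:
    """Analytic excitation: the transducer-face normal velocity w(t).

    w(t) = amplitude * sin(2*pi*f0*t) for t in [0, n_cycles/f0), else 0.
    The waveform is stored in closed form and evaluated at arbitrary
    continuous times, which keeps the baseline simulation path free of
    interpolation error; its time derivative is likewise analytic.

    Attributes
    ----------
    f0 : float
        Center frequency in Hz.
    n_cycles : float
        Burst length in cycles (> 0). Integer or half-integer values keep
        w continuous at the end of its support.
    amplitude : float
        Peak normal velocity in m/s.
    """

    f0: float
    n_cycles: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.n_cycles <= 0:
            raise ValueError("f0 and n_cycles must be positive")

    @property
    def duration(self) -> float:
        """Support length n_cycles/f0 in seconds."""
        return self.n_cycles / self.f0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate w(t) (m/s) at continuous times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        inside = (t >= 0.0) & (t < self.duration)
        out = np.zeros_like(t)
        tw = t[inside]
        out[inside] = self.amplitude * np.sin(2.0 * np.pi * self.f0 * tw)
        return out

    def derivative(self, t: np.ndarray) -> np.ndarray:
        """Evaluate dw/dt (m/s^2) at continuous times ``t`` (s).

        The jump at t=0 (and at the support end for non-half-integer cycle
        counts) is ignored; w(0)=0 so the leading edge is continuous.
        """
        t = np.asarray(t, dtype=float)
        inside = (t >= 0.0) & (t < self.duration)
        out = np.zeros_like(t)
        tw = t[inside]
        w0 = 2.0 * np.pi * self.f0
        out[inside] = self.amplitude * w0 * np.cos(w0 * tw)
        return out


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid t_k = t0 + k/fs, k = 0..n_samples-1.

    ``t0`` may be negative (e.g. when negative transmit delays are in
    play). Internally all waveforms are kept phase-aligned to the lattice
    n/fs so that shifted/convolved waveforms land on common sample times.
    """

    fs: float
    t0: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n_samples - 1) / self.fs


@dataclass(frozen=True)
class TransducerArray:
    """1-D linear array of identical rectangular piston elements.

    Element i is centered at (x_i, 0, 0) with face extents ``width``
    (lateral, x) by ``height`` (elevation, y) and unit normal (0, 0, 1).
    ``pitch`` = width + kerf.
    """

    n_elements: int
    width: float
    height: float
    kerf: float
    centers_x: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def pitch(self) -> float:
        return self.width + self.kerf

    @property
    def element_area(self) -> float:
        return self.width * self.height

    @property
    def positions(self) -> np.ndarray:
        """(M, 3) element center coordinates."""
        out = np.zeros((self.n_elements, 3))
        out[:, 0] = self.centers_x
        return out

    @property
    def aperture_width(self) -> float:
        """Total lateral extent of the active aperture."""
        return (self.n_elements - 1) * self.pitch + self.width


@dataclass(frozen=True)
class DelayVector:
    """Per-element signed firing delays (s) plus any common offset applied.

    ``offset`` records a constant added to every raw delay (used to make
    plane-wave delay sets non-negative); beamforming adds it back into the
    transmit time-of-flight so image positions are unaffected.
    """

    delays: np.ndarray
    offset: float = 0.0

    def __len__(self) -> int:
        return len(self.delays)


def build_linear_array(
    n_elements: int, width: float, height: float, kerf: float
) -> TransducerArray:
    """Build a centered linear array.

    Centers sit at x_i = (i - (M-1)/2) * (width + kerf), i = 0..M-1, so the
    array is symmetric about x = 0 (a single element sits at the origin).

    Parameters are in meters; ``kerf`` (inter-element gap) may be zero.
    """
    if n_elements < 1:
        raise InvalidGeometryError("n_elements must be >= 1")
    if width <= 0 or height <= 0:
        raise InvalidGeometryError("element width and height must be positive")
    if kerf < 0:
        raise InvalidGeometryError("kerf must be non-negative")
    pitch = width + kerf
    idx = np.arange(n_elements, dtype=float)
    centers = (idx - (n_elements - 1) / 2.0) * pitch
    return TransducerArray(
        n_elements=n_elements, width=width, height=height, kerf=kerf,
        centers_x=centers,
    )


def aline_lateral_positions(array: TransducerArray) -> np.ndarray:
    """A-line lateral positions: element centers plus adjacent midpoints.

    Returns 2M-1 sorted positions spaced at pitch/2 for an M-element array
    (a single-element array yields just its center).
    """
    c = array.centers_x
    if array.n_elements < 2:
        return c.copy()
    mids = 0.5 * (c[:-1] + c[1:])
    return np.sort(np.concatenate([c, mids]))


def plane_wave_delays(
    array: TransducerArray,
    angle_deg: float,
    medium: Medium,
    nonnegative: bool = True,
) -> DelayVector:
    """Steering delays for an unfocused plane wave at ``angle_deg``.

    Raw delays tau_i = x_i * sin(theta) / c tilt the wavefront toward +x
    for positive angles. When ``nonnegative`` is set the delays are offset
    so min(tau) = 0 and the offset is recorded: the emitted wavefront then
    reaches the point (x, z) at t = (x sin(theta) + z cos(theta))/c + offset.
    """
    if not abs(angle_deg) < 90.0:
        raise ValueError("|angle| must be < 90 degrees")
    theta = math.radians(angle_deg)
    raw = array.centers_x * math.sin(theta) / medium.sound_speed
    if nonnegative:
        off = -float(raw.min())
        return DelayVector(delays=raw + off, offset=off)
    return DelayVector(delays=raw, offset=0.0)


def focus_delays(
    element_positions: np.ndarray,
    focal_point: np.ndarray,
    medium: Medium,
    reference: np.ndarray | None = None,
) -> DelayVector:
    """Focusing delays for a (sub-)aperture aimed at ``focal_point``.

    tau_i = (|r_f - r_ref| - |r_f - r_i|) / c with r_ref the sub-aperture
    center by default. Elements farther from the focus get smaller
    (possibly negative) delays, i.e. fire earlier, so all wavelets arrive
    at the focus simultaneously — at time |r_f - r_ref|/c relative to the
    reference element's firing instant.
    """
    pos = np.atleast_2d(np.asarray(element_positions, dtype=float))
    rf = np.asarray(focal_point, dtype=float)
    if reference is None:
        reference = pos.mean(axis=0)
    d_ref = float(np.linalg.norm(rf - reference))
    d_i = np.linalg.norm(rf - pos, axis=1)
    if d_ref == 0.0 or np.any(d_i == 0.0):
        raise InvalidGeometryError("focal point coincides with an element")
    return DelayVector(delays=(d_ref - d_i) / medium.sound_speed, offset=0.0)
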