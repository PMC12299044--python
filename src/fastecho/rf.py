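"""RF channel-data synthesis for synthetic aperture, B-mode, and plane
wave imaging.

The received trace for one (transmit event, receive element) pair is the
linear pulse-echo model

    p_r(t) = d/dt [ (1 / (2 rho0 c^2)) * (P_T * p_R)(t) ] * a_s

summed over scatterers, where P_T is the (delayed, apodized) sum of the
transmit intermediates of the event's active elements at the scatterer,
p_R is the receive intermediate of the receive element, a_s the scatterer
amplitude, and * temporal convolution.  Summing/beamforming the transmit
intermediates *before* the convolution is what makes B-mode and plane
wave synthesis cheap: one convolution per (scatterer, receive channel)
instead of one per (transmit element, scatterer, receive channel).

Discretization: convolutions are discrete linear convolutions scaled by
1/fs; the outer time derivative is the centered finite difference at fs
(the margin samples of every trace are zero, so the one-sided endpoint
stencils act on zeros).  The derivative commutes with the sums, so event
traces are exactly the superposition of the single-scatterer pulse-echo
traces — a property the tests rely on.

Transmit delays can be applied three ways (``delay_mode``): re-evaluating
the intermediates at the exact retarded times ('analytic', the baseline),
discrete-time shifting of an undelayed cached bank with linear
interpolation ('cached_linear'), or shifting a 4x-oversampled bank and
decimating back ('cached_upsampled').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numba
import numpy as np
from scipy.signal import fftconvolve

from .field import (
    QuadratureSet,
    Waveform,
    _bank,
    element_quadrature,
)
from .geometry import (
    DelayVector,
    Excitation,
    Medium,
    TimeGrid,
    TransducerArray,
    aline_lateral_positions,
    focus_delays,
    plane_wave_delays,
)

__all__ = [
    "TransmitEvent",
    "RFDataSet",
    "BModeScanConfig",
    "pulse_echo_trace",
    "simulate_synthetic_aperture",
    "simulate_bmode",
    "simulate_plane_wave",
]

_DERIV_KERNEL_NOTE = "centered difference (f[k+1]-f[k-1])*fs/2"


@dataclass(frozen=True)
class TransmitEvent:
    """One transmit firing: active elements, their delays and apodization.

    ``label`` identifies the event (steering angle, A-line, or element
    index); beamforming reads the mode-specific attributes.
    """

    tx_indices: np.ndarray
    delays: DelayVector
    apodization: np.ndarray
    label: str
    angle_deg: float | None = None
    ref_position: np.ndarray | None = None
    aline_x: float | None = None

    def __post_init__(self) -> None:
        n = len(self.tx_indices)
        if len(self.delays) != n or len(self.apodization) != n:
            raise ValueError("delays/apodization must match active element count")
        if np.any(self.apodization < 0) or np.any(self.apodization > 1):
            raise ValueError("apodization weights must lie in [0, 1]")


@dataclass
class RFDataSet:
    """Per-event channel x time received traces on a shared sampling grid."""

    events: list[TransmitEvent]
    data: list[np.ndarray]  # each (M, n_t)
    grid: TimeGrid
    array: TransducerArray
    medium: Medium
    excitation_tx: Excitation
    excitation_rx: Excitation
    mode: str

    @property
    def fs(self) -> float:
        return self.grid.fs

    def __len__(self) -> int:
        return len(self.events)

    def __add__(self, other: "RFDataSet") -> "RFDataSet":
        """Superpose two datasets simulated on the same grid and events
        (e.g. static and moving scatterer populations)."""
        if self.grid != other.grid or len(self) != len(other):
            raise ValueError("datasets must share grid and event structure")
        return RFDataSet(
            events=self.events,
            data=[a + b for a, b in zip(self.data, other.data)],
            grid=self.grid, array=self.array, medium=self.medium,
            excitation_tx=self.excitation_tx, excitation_rx=self.excitation_rx,
            mode=self.mode,
        )


def pulse_echo_trace(
    pT: Waveform, pR: Waveform, amplitude: float, medium: Medium
) -> Waveform:
    """Single-pair pulse-echo trace: d/dt[(pT * pR)/(2 rho0 c^2)] * a_s.

    The discrete convolution is scaled by 1/fs (rectangle rule for the
    continuous integral); the derivative is the centered difference with
    virtual zeros beyond the support, so the output gains one sample on
    each side and starts at t0(pT) + t0(pR) - 1/fs.
    """
    if pT.fs != pR.fs:
        raise ValueError("pT and pR must share the sampling frequency")
    fs = pT.fs
    scale = amplitude / (2.0 * medium.density * medium.sound_speed**2 * fs)
    r = fftconvolve(pT.data, pR.data) * scale
    out = np.convolve(r, [fs / 2.0, 0.0, -fs / 2.0])
    return Waveform(fs=fs, start=pT.start + pR.start - 1, data=out)


def _differentiate(traces: np.ndarray, fs: float) -> np.ndarray:
    """Centered time derivative along the last axis (one-sided at the
    ends, which are margin zeros by construction)."""
    out = np.empty_like(traces)
    out[..., 1:-1] = (traces[..., 2:] - traces[..., :-2]) * (fs / 2.0)
    out[..., 0] = (traces[..., 1] - traces[..., 0]) * fs
    out[..., -1] = (traces[..., -1] - traces[..., -2]) * fs
    return out


def _as_points_amps(scatterers) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(scatterers, "positions"):
        pos, amp = scatterers.positions, scatterers.amplitudes
    else:
        pos, amp = scatterers
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    amp = np.atleast_1d(np.asarray(amp, dtype=float))
    if len(pos) == 0:
        raise ValueError("scatterer field is empty")
    if pos.shape[0] != amp.shape[0] or pos.shape[1] != 3:
        raise ValueError("positions must be (N, 3) with matching amplitudes")
    return pos, amp


def auto_time_grid(
    array: TransducerArray,
    points: np.ndarray,
    events: Sequence[TransmitEvent],
    exc_tx: Excitation,
    exc_rx: Excitation,
    medium: Medium,
    fs: float,
) -> TimeGrid:
    """Lattice-aligned grid covering every event's echoes with margin.

    Sized from element-center distances +/- the element half-diagonal,
    plus both pulse lengths, plus the extreme transmit delays, with a few
    guard samples on each side.
    """
    c = medium.sound_speed
    dc = np.linalg.norm(
        array.positions[:, None, :] - points[None, :, :], axis=2
    )  # (M, N)
    half_diag = 0.5 * np.hypot(array.width, array.height)
    # upper margin budgets the full element diagonal: the per-pair
    # waveform windows share a bank-wide support length, so a nearby
    # pair's window can extend by the worst pair's retarded-time spread
    diag = 2.0 * half_diag
    t_lo, t_hi = np.inf, -np.inf
    for ev in events:
        tau = ev.delays.delays
        dtx = dc[ev.tx_indices]
        tx_lo = (dtx / c + tau[:, None]).min() - half_diag / c
        tx_hi = (dtx / c + tau[:, None]).max() + diag / c + exc_tx.duration
        rx_lo = dc.min() / c - half_diag / c
        rx_hi = dc.max() / c + diag / c + exc_rx.duration
        t_lo = min(t_lo, tx_lo + rx_lo)
        t_hi = max(t_hi, tx_hi + rx_hi)
    start = int(np.floor(t_lo * fs)) - 4
    n = int(np.ceil((t_hi - t_lo) * fs)) + 24
    return TimeGrid(fs=fs, t0=start / fs, n_samples=n)


def _shift_bank_linear(
    data: np.ndarray, start: np.ndarray, delay: float, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolation shift of a waveform bank (..., L) by one delay."""
    s = delay * fs
    k = int(np.floor(s))
    f = s - k
    out = np.zeros(data.shape[:-1] + (data.shape[-1] + 1,))
    out[..., :-1] = (1.0 - f) * data
    out[..., 1:] += f * data
    return out, start + k


def _transmit_sum_cached(
    tx_centers, tx_tau, tx_apod, pts, exc_tx, medium, fs, quad, mode
):
    """Transmit-summed waveforms per scatterer via the cached shifting
    paths. Returns (P (n, Lp), startP (n,))."""
    if mode == "cached_upsampled":
        data4, start4 = _bank(tx_centers, pts, exc_tx, medium, 4 * fs, quad)
        banks = []
        for i in range(len(tx_centers)):
            sh, st4 = _shift_bank_linear(data4[i], start4[i], tx_tau[i], 4 * fs)
            # decimate each row to the base lattice (congruent to 0 mod 4)
            j0 = (-st4) % 4
            L4 = sh.shape[-1]
            Lb = (L4 + 3) // 4
            dec = np.zeros((sh.shape[0], Lb))
            stb = np.empty_like(st4)
            for r in range(sh.shape[0]):
                row = sh[r, j0[r] :: 4]
                dec[r, : len(row)] = row
                stb[r] = (st4[r] + j0[r]) // 4
            banks.append((tx_apod[i] * dec, stb))
    else:  # cached_linear
        data, start = _bank(tx_centers, pts, exc_tx, medium, fs, quad)
        banks = []
        for i in range(len(tx_centers)):
            sh, st = _shift_bank_linear(data[i], start[i], tx_tau[i], fs)
            banks.append((tx_apod[i] * sh, st))
    n = len(pts)
    s_min = np.min([st for _, st in banks], axis=0)
    s_max = np.max(
        [st + b.shape[-1] for b, st in banks], axis=0
    )
    startP = s_min - 1
    Lp = int((s_max - startP).max()) + 1
    P = np.zeros((n, Lp))
    for b, st in banks:
        off = st - startP
        idx = off[:, None] + np.arange(b.shape[-1])[None, :]
        np.add.at(P, (np.arange(n)[:, None], idx), b)
    return P, startP


def _transmit_sum_analytic(tx_centers, tx_tau, tx_apod, pts, exc_tx, medium, fs, quad):
    """Transmit-summed waveforms per scatterer: per-element intermediates
    evaluated with the delays folded into the retarded times (exact),
    apodized, and accumulated.  Returns (P (n, Lp), startP (n,))."""
    data, start = _bank(tx_centers, pts, exc_tx, medium, fs, quad, delays=tx_tau)
    data = data * tx_apod[:, None, None]
    Et, n, Lb = data.shape
    startP = start.min(axis=0) - 1
    Lp = int((start.max(axis=0) - startP).max()) + Lb + 2
    off = start - startP[None, :]  # (Et, n)
    flat = (
        np.arange(n)[None, :, None] * Lp
        + off[:, :, None]
        + np.arange(Lb)[None, None, :]
    ).ravel()
    P = np.bincount(flat, weights=data.ravel(), minlength=n * Lp).reshape(n, Lp)
    return P, startP


@numba.njit(cache=True, fastmath=True)
def _conv_accumulate(P, sP, pR, sR, g0, acc):  # pragma: no cover
    """Fused per-(scatterer, channel) linear convolution and trace
    accumulation: acc[j] += (P[n] * pR[j, n]) placed at its start sample.
    Samples falling off the grid are structurally zero (bank padding) and
    are skipped."""
    n, Lp = P.shape
    M, _, Lr = pR.shape
    n_t = acc.shape[1]
    for i in range(n):
        base = sP[i] - g0
        for j in range(M):
            b = base + sR[j, i]
            for k2 in range(Lr):
                v = pR[j, i, k2]
                if v == 0.0:
                    continue
                o = b + k2
                k1_lo = -o if o < 0 else 0
                k1_hi = min(Lp, n_t - o)
                for k1 in range(k1_lo, k1_hi):
                    acc[j, o + k1] += v * P[i, k1]


def _event_traces(
    array: TransducerArray,
    event: TransmitEvent,
    points: np.ndarray,
    amps: np.ndarray,
    exc_tx: Excitation,
    exc_rx: Excitation,
    medium: Medium,
    grid: TimeGrid,
    quad: QuadratureSet,
    delay_mode: str = "analytic",
    chunk: int = 256,
) -> np.ndarray:
    """All-channel traces (M, n_t) for one transmit event."""
    M = array.n_elements
    fs = grid.fs
    n_t = grid.n_samples
    g0 = int(round(grid.t0 * fs))
    c = medium.sound_speed
    tx_centers = array.positions[event.tx_indices]
    # DelayVector.delays are the applied firing delays (any non-negativity
    # offset is already folded in; .offset only records it for beamforming)
    tx_tau = event.delays.delays
    tx_apod = event.apodization
    acc = np.zeros((M, n_t))
    conv_scale = 1.0 / (2.0 * medium.density * c**2 * fs)
    for lo in range(0, len(points), chunk):
        pts = points[lo : lo + chunk]
        a = amps[lo : lo + chunk]
        n = len(pts)
        # --- transmit side: per-scatterer beamformed sum over elements ---
        if delay_mode == "analytic":
            P, startP = _transmit_sum_analytic(
                tx_centers, tx_tau, tx_apod, pts, exc_tx, medium, fs, quad
            )
        else:
            P, startP = _transmit_sum_cached(
                tx_centers, tx_tau, tx_apod, pts,
                exc_tx, medium, fs, quad, delay_mode,
            )
        P = P * (a * conv_scale)[:, None]
        # --- receive side: undelayed intermediates, all channels ---
        pR, startR = _bank(array.positions, pts, exc_rx, medium, fs, quad)
        # --- convolve and accumulate ---
        _conv_accumulate(
            P, startP, np.ascontiguousarray(pR), startR, g0, acc
        )
    return _differentiate(acc, fs)


def _simulate(
    array, scatterers, exc_tx, exc_rx, medium, events, fs, grid, quad,
    delay_mode, mode,
) -> RFDataSet:
    points, amps = _as_points_amps(scatterers)
    # depth-sort so each processing chunk holds scatterers with similar
    # echo support lengths (keeps window/convolution sizes tight)
    order = np.argsort(points[:, 2], kind="stable")
    points, amps = points[order], amps[order]
    if quad is None:
        quad = element_quadrature(array)
    if exc_rx is None:
        exc_rx = exc_tx
    if grid is None:
        grid = auto_time_grid(array, points, events, exc_tx, exc_rx, medium, fs)
    elif grid.fs != fs:
        raise ValueError("grid fs mismatch")
    data = [
        _event_traces(
            array, ev, points, amps, exc_tx, exc_rx, medium, grid, quad,
            delay_mode=delay_mode,
        )
        for ev in events
    ]
    return RFDataSet(
        events=list(events), data=data, grid=grid, array=array, medium=medium,
        excitation_tx=exc_tx, excitation_rx=exc_rx, mode=mode,
    )


def simulate_synthetic_aperture(
    array: TransducerArray,
    scatterers,
    excitation: Excitation,
    medium: Medium,
    fs: float,
    excitation_rx: Excitation | None = None,
    quad: QuadratureSet | None = None,
    grid: TimeGrid | None = None,
    delay_mode: str = "analytic",
    tx_elements: Sequence[int] | None = None,
) -> RFDataSet:
    """Synthetic aperture RF data: one event per transmit element (each
    element excited individually, all M channels received)."""
    tx = range(array.n_elements) if tx_elements is None else tx_elements
    events = [
        TransmitEvent(
            tx_indices=np.array([i]),
            delays=DelayVector(delays=np.zeros(1)),
            apodization=np.ones(1),
            label=f"sa{i:03d}",
        )
        for i in tx
    ]
    return _simulate(
        array, scatterers, excitation, excitation_rx, medium, events, fs,
        grid, quad, delay_mode, "sa",
    )


@dataclass(frozen=True)
class BModeScanConfig:
    """Walking-aperture scan: ``n_subaperture`` elements, Hanning-apodized,
    focused at ``focus_depth`` on transmit, one event per A-line."""

    n_subaperture: int = 64
    focus_depth: float = 0.060
    aline_positions: np.ndarray | None = None

    def resolve_alines(self, array: TransducerArray) -> np.ndarray:
        if self.aline_positions is not None:
            return np.asarray(self.aline_positions, dtype=float)
        return aline_lateral_positions(array)


def simulate_bmode(
    array: TransducerArray,
    scatterers,
    excitation: Excitation,
    medium: Medium,
    fs: float,
    scan_config: BModeScanConfig | None = None,
    excitation_rx: Excitation | None = None,
    quad: QuadratureSet | None = None,
    grid: TimeGrid | None = None,
    delay_mode: str = "analytic",
) -> RFDataSet:
    """B-mode RF data: the sub-aperture walks across the array, centered
    as close to each A-line as the element pitch allows and clamped at the
    array edges.  Transmit intermediates are summed (with focusing delays
    and Hanning apodization) before convolution."""
    cfg = scan_config or BModeScanConfig()
    n_sub = cfg.n_subaperture
    if n_sub > array.n_elements:
        raise ValueError("sub-aperture exceeds the array")
    alines = cfg.resolve_alines(array)
    centers = array.centers_x
    events = []
    for x in alines:
        s = int(round((x - centers[0]) / array.pitch - (n_sub - 1) / 2.0))
        s = int(np.clip(s, 0, array.n_elements - n_sub))
        idx = np.arange(s, s + n_sub)
        pos = array.positions[idx]
        focal = np.array([x, 0.0, cfg.focus_depth])
        dv = focus_delays(pos, focal, medium)
        apod = np.hanning(n_sub) if n_sub > 1 else np.ones(1)
        events.append(
            TransmitEvent(
                tx_indices=idx, delays=dv, apodization=apod,
                label=f"aline@{x * 1e3:+.3f}mm",
                ref_position=pos.mean(axis=0), aline_x=float(x),
            )
        )
    return _simulate(
        array, scatterers, excitation, excitation_rx, medium, events, fs,
        grid, quad, delay_mode, "bmode",
    )


def simulate_plane_wave(
    array: TransducerArray,
    scatterers,
    excitation: Excitation,
    medium: Medium,
    fs: float,
    angles_deg: Sequence[float],
    excitation_rx: Excitation | None = None,
    quad: QuadratureSet | None = None,
    grid: TimeGrid | None = None,
    delay_mode: str = "analytic",
) -> RFDataSet:
    """Plane wave RF data: one event per steering angle; all M elements
    transmit with linear steering delays (offset to be non-negative, the
    offset recorded on the event), receive is element-wise."""
    if len(angles_deg) == 0:
        raise ValueError("at least one steering angle is required")
    events = []
    for ang in angles_deg:
        dv = plane_wave_delays(array, ang, medium)
        events.append(
            TransmitEvent(
                tx_indices=np.arange(array.n_elements),
                delays=dv,
                apodization=np.ones(array.n_elements),
                label=f"pw{ang:+.1f}deg",
                angle_deg=float(ang),
            )
        )
    return _simulate(
        array, scatterers, excitation, excitation_rx, medium, events, fs,
        grid, quad, delay_mode, "pw",
    )
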