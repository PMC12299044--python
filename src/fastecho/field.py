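"""Transmit/receive intermediate pressure fields at scatterer locations.

The transmit intermediate p_T (and its receive twin p_R) is the transient
pressure radiated by one rectangular piston element, evaluated at a point
scatterer, for a face normal velocity w(t):

    p(r, t) = (rho0 / 2 pi) * Int_face  dw/dt(t - d/c) / d  dA .

Because dw/dt of a rectangular-envelope sinusoid is discontinuous at the
burst edges, naive point sampling of this integral converges only at
first order in the node count.  Both evaluation schemes here therefore
integrate the time dimension analytically and reserve numerical
quadrature for the smooth spatial remainder — the property that makes
fast-nearfield-style transient solvers converge with a handful of
abscissas:

* Gauss-Legendre sets (:func:`element_quadrature`): per lateral abscissa,
  the elevation integral is clipped exactly to the excitation support
  (the integrand is then smooth) and evaluated with ``order_y``
  Gauss-Legendre nodes per smooth piece; each node folds the lateral
  sub-aperture's retarded-time spread in closed form (boxcar average of
  dw/dt plus the second-order mean-delay correction).
* Uniform sets (:func:`uniform_quadrature`): dense sub-element
  discretization where each cell contributes the exact time-average of
  dw/dt over its own retarded-time span (from the exact nearest/farthest
  cell distances).  At lambda/8 spacing this is the brute-force accuracy
  oracle; unlike plain point sampling it converges at second order, so
  the oracle is itself converged to ~1e-4.

Waveforms are sampled on the global lattice t_k = k/fs (k integer,
possibly negative) so that delayed, convolved, and accumulated signals
always share sample phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numba
import numpy as np
from numpy.polynomial.legendre import leggauss

from .geometry import Excitation, Medium, TimeGrid, TransducerArray

__all__ = [
    "Waveform",
    "QuadratureSet",
    "IntermediateCache",
    "element_quadrature",
    "uniform_quadrature",
    "transient_pressure",
    "delayed_copy",
    "build_intermediate_cache",
]

DelayMode = Literal["analytic", "cached_linear", "cached_upsampled"]

_TINY = 1e-300
_HL_EPS = 1e-14  # below this lateral delay halfwidth, point-sample dw/dt


class SingularGeometryError(ValueError):
    """Raised when a field point touches the radiating surface."""


@dataclass
class Waveform:
    """Sampled waveform on the lattice t_k = (start + k)/fs.

    ``analytic``, when present, re-evaluates the generating expression at
    arbitrary continuous times (used by the 'analytic' delay mode).
    ``upsampled`` optionally holds the same waveform sampled at 4*fs.
    """

    fs: float
    start: int
    data: np.ndarray
    analytic: Callable[[np.ndarray], np.ndarray] | None = None
    upsampled: "Waveform | None" = field(default=None, repr=False)

    @property
    def t0(self) -> float:
        return self.start / self.fs

    @property
    def times(self) -> np.ndarray:
        return (self.start + np.arange(len(self.data))) / self.fs

    def on_grid(self, grid: TimeGrid) -> np.ndarray:
        """Embed into ``grid`` (zero outside support).  Grid t0 must sit
        on the same lattice."""
        g0 = int(round(grid.t0 * self.fs))
        out = np.zeros(grid.n_samples)
        a = self.start - g0
        b = a + len(self.data)
        lo, hi = max(a, 0), min(b, grid.n_samples)
        if lo < hi:
            out[lo:hi] = self.data[lo - a : hi - a]
        return out


@dataclass(frozen=True)
class QuadratureSet:
    """Quadrature rule on the element face.

    ``offsets`` are (Q, 2) node coordinates relative to the element
    center, ``weights`` (Q,) area weights summing to width*height.
    ``kind`` selects the evaluation scheme described in the module
    docstring; Gauss sets carry the tensor orders and face extents,
    uniform sets carry per-cell extents for the retarded-time windows.
    """

    offsets: np.ndarray
    weights: np.ndarray
    kind: Literal["gauss", "uniform"] = "gauss"
    order_x: int = 1
    order_y: int = 1
    width: float = 0.0
    height: float = 0.0
    cell_extents: np.ndarray | None = None

    @property
    def order(self) -> int:
        return len(self.weights)


def element_quadrature(
    array: TransducerArray, order_x: int = 1, order_y: int = 6
) -> QuadratureSet:
    """Tensor-product Gauss-Legendre quadrature on the element face.

    ``order_x`` spans the lateral width, ``order_y`` the elevation
    height.  The default (1, 6) places six abscissas along the 7 mm-class
    elevation axis — the long dimension, where the retarded-time spread
    is largest — and one across the sub-wavelength width; the nearfield
    configuration 2 x 25 mirrors a 2-across / 25-along sub-element
    split.  Weights are scaled so they sum to the element area.
    """
    if order_x < 1 or order_y < 1:
        raise ValueError("quadrature orders must be >= 1")
    nx, wx = leggauss(order_x)
    ny, wy = leggauss(order_y)
    gx = nx * array.width / 2.0
    gy = ny * array.height / 2.0
    wx = wx * array.width / 2.0
    wy = wy * array.height / 2.0
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    W = np.outer(wx, wy)
    return QuadratureSet(
        offsets=np.column_stack([X.ravel(), Y.ravel()]),
        weights=W.ravel(),
        kind="gauss",
        order_x=order_x,
        order_y=order_y,
        width=array.width,
        height=array.height,
    )


def uniform_quadrature(array: TransducerArray, spacing: float) -> QuadratureSet:
    """Uniform sub-element discretization at <= ``spacing`` (m).

    The brute-force realization of the Rayleigh integral used as the
    accuracy oracle (e.g. at lambda/8 spacing); each cell's contribution
    is time-integrated exactly over the cell's retarded-time span.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    nx = max(1, int(np.ceil(array.width / spacing)))
    ny = max(1, int(np.ceil(array.height / spacing)))
    ex_, ey_ = array.width / nx, array.height / ny
    ex = (np.arange(nx) + 0.5) * ex_ - array.width / 2.0
    ey = (np.arange(ny) + 0.5) * ey_ - array.height / 2.0
    X, Y = np.meshgrid(ex, ey, indexing="ij")
    w = np.full(nx * ny, array.element_area / (nx * ny))
    return QuadratureSet(
        offsets=np.column_stack([X.ravel(), Y.ravel()]),
        weights=w,
        kind="uniform",
        order_x=nx,
        order_y=ny,
        width=array.width,
        height=array.height,
        cell_extents=np.tile([ex_, ey_], (nx * ny, 1)),
    )


def _node_positions(center: np.ndarray, quad: QuadratureSet) -> np.ndarray:
    """(Q, 3) absolute node coordinates for an element centered at
    ``center`` in the z=0 plane."""
    pos = np.zeros((quad.order, 3))
    pos[:, 0] = center[0] + quad.offsets[:, 0]
    pos[:, 1] = center[1] + quad.offsets[:, 1]
    pos[:, 2] = center[2]
    return pos


@numba.njit(cache=True, fastmath=True)
def _gauss_kernel(
    ax, ay, az, t, xl, ext, un, uw, height, c, T, om, amp, rho
):  # pragma: no cover - exercised via _eval_gauss
    """Clipped composite Gauss-Legendre evaluation (scalar inner loops).

    For each (field point p, time sample k): per lateral abscissa, the
    elevation integration domain is clipped exactly to the excitation
    support (|u| between ulo and uhi), leaving a smooth integrand that
    ``len(un)`` Gauss-Legendre nodes per smooth piece integrate to high
    order; each node applies the exact boxcar average of dw/dt over the
    lateral strip's retarded-time spread.  The excitation is the
    rectangular-envelope sinusoid amp*sin(om*t) on [0, T).
    """
    P, L = t.shape
    out = np.zeros((P, L))
    nlat = xl.size
    ny = un.size
    tau_fix = np.empty(ny)
    hl_fix = np.empty(ny)
    cf2 = np.empty(ny)
    ctau = np.empty(ny)
    stau = np.empty(ny)
    cf_fix = np.empty(ny)
    for p in range(P):
        ua = -height / 2.0 - ay[p]
        ub = height / 2.0 - ay[p]
        umax2 = max(ua * ua, ub * ub)
        for l in range(nlat):
            dx = xl[l] - ax[p]
            r2 = dx * dx + az[p] * az[p]
            r = np.sqrt(r2)
            # second-order lateral mean delay (wavefront curvature across
            # the strip), folded into the effective strip distance
            reff = r + (1.0 - (dx / r) ** 2) * (ext[l] * ext[l] / 24.0) / r
            reff2 = reff * reff
            if ua <= 0.0 <= ub:
                umin2 = 0.0
            else:
                umin2 = min(ua * ua, ub * ub)
            t_lo = np.sqrt(reff2 + umin2) / c
            t_hi = np.sqrt(reff2 + umax2) / c + T
            hl_c = 0.5 * abs(dx) * ext[l] / c
            # fixed nodes for samples where the whole strip is insonified;
            # the boxcar average of dw/dt collapses to
            # amp*cos(om*(t-tau))*sin(om*hl)/hl, and the cosine is split
            # by angle addition so the per-node work is two FMAs
            halfF = 0.5 * (ub - ua)
            midF = 0.5 * (ub + ua)
            for m in range(ny):
                u = midF + halfF * un[m]
                d = np.sqrt(reff2 + u * u)
                tau_fix[m] = d / c
                hl = hl_c / d
                hl_fix[m] = hl
                cf_fix[m] = ext[l] * uw[m] * halfF / d
                slim = om if hl <= 1e-14 else np.sin(om * hl) / hl
                cf2[m] = cf_fix[m] * amp * slim
                ctau[m] = np.cos(om * tau_fix[m])
                stau[m] = np.sin(om * tau_fix[m])
            for k in range(L):
                tt = t[p, k]
                if tt <= t_lo or tt >= t_hi:
                    continue
                arg = (c * tt) ** 2 - reff2
                if arg <= 0.0:
                    continue
                uhi2 = arg
                ulo2 = -1.0
                if tt > T:
                    a2 = (c * (tt - T)) ** 2 - reff2
                    if a2 > 0.0:
                        ulo2 = a2
                if uhi2 >= umax2 and ulo2 <= umin2:
                    # full coverage: precomputed nodes
                    cos_t = np.cos(om * tt)
                    sin_t = np.sin(om * tt)
                    for m in range(ny):
                        a = tt - tau_fix[m]
                        hl = hl_fix[m]
                        if a >= hl and a < T - hl:
                            # cos(om*(tt - tau)) via angle addition
                            out[p, k] += cf2[m] * (
                                cos_t * ctau[m] + sin_t * stau[m]
                            )
                        elif a + hl > 0.0 and a - hl < T:
                            # node window straddles a burst edge
                            if hl > 1e-14:
                                ap = a + hl
                                am = a - hl
                                wp = (
                                    amp * np.sin(om * ap)
                                    if 0.0 <= ap < T
                                    else 0.0
                                )
                                wm = (
                                    amp * np.sin(om * am)
                                    if 0.0 <= am < T
                                    else 0.0
                                )
                                out[p, k] += cf_fix[m] * (wp - wm) / (2.0 * hl)
                            elif 0.0 <= a < T:
                                out[p, k] += (
                                    cf_fix[m] * amp * om * np.cos(om * a)
                                )
                    continue
                uhi = np.sqrt(uhi2)
                ulo = np.sqrt(ulo2) if ulo2 > 0.0 else 0.0
                # up to two smooth pieces: |u| in [ulo, uhi] within [ua, ub]
                for s in range(2):
                    if ulo > 0.0:
                        if s == 0:
                            lo = max(ua, -uhi)
                            hi = min(ub, -ulo)
                        else:
                            lo = max(ua, ulo)
                            hi = min(ub, uhi)
                    else:
                        if s == 1:
                            break
                        lo = max(ua, -uhi)
                        hi = min(ub, uhi)
                    if hi <= lo:
                        continue
                    half = 0.5 * (hi - lo)
                    mid = 0.5 * (hi + lo)
                    for m in range(ny):
                        u = mid + half * un[m]
                        d = np.sqrt(reff2 + u * u)
                        hl = hl_c / d
                        a = tt - d / c
                        if hl > 1e-14:
                            # exact average of dw/dt over [a-hl, a+hl]
                            ap = a + hl
                            am = a - hl
                            wp = amp * np.sin(om * ap) if 0.0 <= ap < T else 0.0
                            wm = amp * np.sin(om * am) if 0.0 <= am < T else 0.0
                            v = (wp - wm) / (2.0 * hl)
                        else:
                            v = amp * om * np.cos(om * a) if 0.0 <= a < T else 0.0
                        out[p, k] += ext[l] * uw[m] * half * v / d
    return out * (rho / (2.0 * np.pi))


def _eval_gauss(
    ax: np.ndarray,
    ay: np.ndarray,
    az: np.ndarray,
    t: np.ndarray,
    exc: Excitation,
    medium: Medium,
    quad: QuadratureSet,
) -> np.ndarray:
    """Clipped composite Gauss-Legendre evaluation (see module docstring).

    (ax, ay, az): field-point offsets from the element center, shapes
    (P,); t: times (P, L).  Returns pressure (P, L) in Pa.
    """
    xn, xw = leggauss(quad.order_x)
    un, uw = leggauss(quad.order_y)
    t2 = np.ascontiguousarray(np.broadcast_to(t, (len(ax), t.shape[-1])), dtype=float)
    return _gauss_kernel(
        np.ascontiguousarray(ax, dtype=float),
        np.ascontiguousarray(ay, dtype=float),
        np.ascontiguousarray(az, dtype=float),
        t2,
        xn * quad.width / 2.0,
        xw * quad.width / 2.0,
        un,
        uw,
        quad.height,
        medium.sound_speed,
        exc.duration,
        2.0 * np.pi * exc.f0,
        exc.amplitude,
        medium.density,
    )


@numba.njit(cache=True, fastmath=True)
def _uniform_kernel(
    ax, ay, az, t, ox, oy, wq, ex2, ey2, c, T, om, amp, rho
):  # pragma: no cover - exercised via _eval_uniform
    """Dense-cell evaluation with exact per-cell retarded-time windows:
    each sub-element contributes the exact boxcar average of dw/dt over
    [dmin, dmax]/c of its own cell, centered on the window midpoint."""
    P, L = t.shape
    Q = ox.size
    out = np.zeros((P, L))
    for p in range(P):
        for q in range(Q):
            dx = abs(ox[q] - ax[p])
            dy = abs(oy[q] - ay[p])
            d = np.sqrt(dx * dx + dy * dy + az[p] * az[p])
            dmax = np.sqrt(
                (dx + ex2[q]) ** 2 + (dy + ey2[q]) ** 2 + az[p] * az[p]
            )
            gx = dx - ex2[q]
            gy = dy - ey2[q]
            if gx < 0.0:
                gx = 0.0
            if gy < 0.0:
                gy = 0.0
            dmin = np.sqrt(gx * gx + gy * gy + az[p] * az[p])
            h = (dmax - dmin) / (2.0 * c)
            tc = (dmax + dmin) / (2.0 * c)
            coef = wq[q] / d
            if h <= 1e-14:
                for k in range(L):
                    a = t[p, k] - tc
                    if 0.0 <= a < T:
                        out[p, k] += coef * amp * om * np.cos(om * a)
                continue
            c2 = coef * amp * np.sin(om * h) / h * 0.5
            ctc = np.cos(om * tc)
            stc = np.sin(om * tc)
            inv2h = 1.0 / (2.0 * h)
            for k in range(L):
                a = t[p, k] - tc
                if a + h <= 0.0 or a - h >= T:
                    continue
                if a >= h and a < T - h:
                    # interior: boxcar average collapses to
                    # amp*cos(om*a)*sin(om*h)/h (angle-addition form)
                    cos_t = np.cos(om * t[p, k])
                    sin_t = np.sin(om * t[p, k])
                    out[p, k] += 2.0 * c2 * (cos_t * ctc + sin_t * stc)
                else:
                    ap = a + h
                    am = a - h
                    wp = amp * np.sin(om * ap) if 0.0 <= ap < T else 0.0
                    wm = amp * np.sin(om * am) if 0.0 <= am < T else 0.0
                    out[p, k] += coef * (wp - wm) * inv2h
    return out * (rho / (2.0 * np.pi))


def _eval_uniform(
    ax: np.ndarray,
    ay: np.ndarray,
    az: np.ndarray,
    t: np.ndarray,
    exc: Excitation,
    medium: Medium,
    quad: QuadratureSet,
) -> np.ndarray:
    """Dense-cell evaluation with exact per-cell retarded-time windows."""
    dmin, _ = _rect_distance_range(ax, ay, az, quad.width, quad.height)
    if np.any(dmin <= 0.0):
        raise SingularGeometryError("a field point lies on an element face")
    t2 = np.ascontiguousarray(np.broadcast_to(t, (len(ax), t.shape[-1])), dtype=float)
    return _uniform_kernel(
        np.ascontiguousarray(ax, dtype=float),
        np.ascontiguousarray(ay, dtype=float),
        np.ascontiguousarray(az, dtype=float),
        t2,
        np.ascontiguousarray(quad.offsets[:, 0]),
        np.ascontiguousarray(quad.offsets[:, 1]),
        np.ascontiguousarray(quad.weights),
        np.ascontiguousarray(quad.cell_extents[:, 0] / 2.0),
        np.ascontiguousarray(quad.cell_extents[:, 1] / 2.0),
        medium.sound_speed,
        exc.duration,
        2.0 * np.pi * exc.f0,
        exc.amplitude,
        medium.density,
    )


def _eval_quadrature(ax, ay, az, t, exc, medium, quad) -> np.ndarray:
    ax = np.atleast_1d(np.asarray(ax, dtype=float))
    ay = np.atleast_1d(np.asarray(ay, dtype=float))
    az = np.atleast_1d(np.asarray(az, dtype=float))
    t = np.asarray(t, dtype=float)
    if t.ndim == 1:
        t = t[None, :]
    if quad.kind == "gauss":
        return _eval_gauss(ax, ay, az, t, exc, medium, quad)
    return _eval_uniform(ax, ay, az, t, exc, medium, quad)


def _rect_distance_range(
    ax: np.ndarray, ay: np.ndarray, az: np.ndarray, width: float, height: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest/farthest distance from field points (offsets from
    the element center) to the element rectangle."""
    cx = np.clip(ax, -width / 2.0, width / 2.0)
    cy = np.clip(ay, -height / 2.0, height / 2.0)
    dmin = np.sqrt((ax - cx) ** 2 + (ay - cy) ** 2 + az**2)
    dmax = np.sqrt(
        (np.abs(ax) + width / 2.0) ** 2 + (np.abs(ay) + height / 2.0) ** 2 + az**2
    )
    return dmin, dmax


def transient_pressure(
    center: np.ndarray,
    point: np.ndarray,
    excitation: Excitation,
    medium: Medium,
    quad: QuadratureSet,
    grid: TimeGrid | None = None,
    fs: float | None = None,
) -> Waveform:
    """Transient pressure (Pa) of one rectangular element at ``point``.

    Either pass a ``grid`` (the waveform is returned on it) or an ``fs``
    (the support window is auto-sized: causal from the nearest-face
    time-of-flight, ending at the farthest one plus the pulse duration).
    The returned waveform carries an ``analytic`` re-evaluator for
    interpolation-free delaying.
    """
    center = np.asarray(center, dtype=float)
    point = np.asarray(point, dtype=float)
    ax = np.array([point[0] - center[0]])
    ay = np.array([point[1] - center[1]])
    az = np.array([point[2] - center[2]])
    w = quad.width if quad.width > 0 else 2 * np.abs(quad.offsets[:, 0]).max()
    h = quad.height if quad.height > 0 else 2 * np.abs(quad.offsets[:, 1]).max()
    dmin, dmax = _rect_distance_range(ax, ay, az, w, h)
    if dmin[0] <= 0.0:
        raise SingularGeometryError("field point lies on the element face")
    c = medium.sound_speed

    def analytic(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return _eval_quadrature(ax, ay, az, t[None, :], excitation, medium, quad)[0]

    if grid is None:
        if fs is None:
            raise ValueError("provide either grid or fs")
        start = int(np.floor(dmin[0] / c * fs)) - 1
        stop = int(np.ceil((dmax[0] / c + excitation.duration) * fs)) + 2
        n = stop - start
    else:
        fs = grid.fs
        start = int(round(grid.t0 * fs))
        n = grid.n_samples
    t = (start + np.arange(n)) / fs
    return Waveform(fs=fs, start=start, data=analytic(t), analytic=analytic)


def delayed_copy(waveform: Waveform, delay: float, mode: DelayMode) -> Waveform:
    """Time-shift ``waveform`` by ``delay`` seconds: output(t) = input(t - delay).

    Modes
    -----
    analytic
        Re-evaluate the generating expression at the shifted retarded
        times (exact; requires the waveform to carry an ``analytic``
        callable).
    cached_linear
        Discrete-time shifting with linear interpolation on the base
        sampling grid.
    cached_upsampled
        Linear-interpolation shifting on a 4x-oversampled copy of the
        waveform, then decimation back to the base lattice (every 4th
        sample, aligned; no anti-alias filter — the shift is pure delay,
        so no new frequency content is created).
    """
    fs = waveform.fs
    shift = delay * fs
    k = int(np.floor(shift))
    f = shift - k
    if mode == "analytic":
        if waveform.analytic is None:
            raise ValueError("analytic delay mode requires a re-evaluable waveform")
        start = waveform.start + k
        n = len(waveform.data) + 1
        t = (start + np.arange(n)) / fs
        return Waveform(
            fs=fs, start=start, data=waveform.analytic(t - delay),
            analytic=lambda tt, _d=delay, _a=waveform.analytic: _a(tt - _d),
        )
    if mode == "cached_linear":
        data = waveform.data
        if f == 0.0:
            return Waveform(fs=fs, start=waveform.start + k, data=data.copy())
        out = np.empty(len(data) + 1)
        out[:-1] = (1.0 - f) * data
        out[-1] = 0.0
        out[1:] += f * data
        return Waveform(fs=fs, start=waveform.start + k, data=out)
    if mode == "cached_upsampled":
        up = waveform.upsampled
        if up is None:
            raise ValueError("cached_upsampled mode requires an upsampled bank")
        shifted4 = delayed_copy(up, delay, "cached_linear")
        # decimate: keep lattice-4 samples congruent to 0 mod 4
        j0 = (-shifted4.start) % 4
        data = shifted4.data[j0::4]
        start = (shifted4.start + j0) // 4
        return Waveform(fs=fs, start=start, data=data.copy())
    raise ValueError(f"unknown delay mode: {mode}")


def _bank(
    centers: np.ndarray,
    points: np.ndarray,
    excitation: Excitation,
    medium: Medium,
    fs: float,
    quad: QuadratureSet,
    delays: np.ndarray | None = None,
    pair_chunk: int = 16384,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate intermediates for all (element, point) pairs.

    Optional per-element ``delays`` are folded into the evaluation times
    (exact, 'analytic' handling).  Returns (data (E, N, L), start (E, N))
    where L is the maximum support length across pairs.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    points = np.atleast_2d(np.asarray(points, dtype=float))
    E, N = len(centers), len(points)
    ax = points[None, :, 0] - centers[:, None, 0]
    ay = points[None, :, 1] - centers[:, None, 1]
    az = points[None, :, 2] - centers[:, None, 2]
    dmin, dmax = _rect_distance_range(ax, ay, az, quad.width, quad.height)
    if np.any(dmin <= 0.0):
        raise SingularGeometryError("a field point lies on an element face")
    c = medium.sound_speed
    tau = np.zeros((E, 1)) if delays is None else np.asarray(delays)[:, None]
    t_lo = dmin / c + tau
    start = np.floor(t_lo * fs).astype(np.int64) - 1
    L = int(np.ceil(((dmax - dmin) / c).max() * fs + excitation.duration * fs)) + 3
    axf, ayf, azf = ax.ravel(), ay.ravel(), az.ravel()
    sf = start.ravel()
    tf = np.broadcast_to(tau, (E, N)).ravel()
    data = np.empty((E * N, L))
    for lo in range(0, E * N, pair_chunk):
        hi = min(lo + pair_chunk, E * N)
        t = (sf[lo:hi, None] + np.arange(L)[None, :]) / fs - tf[lo:hi, None]
        data[lo:hi] = _eval_quadrature(
            axf[lo:hi], ayf[lo:hi], azf[lo:hi], t, excitation, medium, quad
        )
    return data.reshape(E, N, L), start


@dataclass
class IntermediateCache:
    """Bank of undelayed per-(element, scatterer) intermediate waveforms.

    Waveforms are stored as a padded array ``data[e, n]`` with per-pair
    start indices on the base lattice; if ``upsample`` is 4, a parallel
    bank sampled at 4*fs is held for the upsampled shifting mode.  Any
    delayed intermediate is reconstructed with :func:`delayed_copy`.
    """

    fs: float
    data: np.ndarray  # (E, N, L)
    start: np.ndarray  # (E, N) int
    upsample: int = 1
    data4: np.ndarray | None = None
    start4: np.ndarray | None = None

    @property
    def n_elements(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    def get(self, element: int, point: int) -> Waveform:
        w = Waveform(
            fs=self.fs, start=int(self.start[element, point]),
            data=self.data[element, point],
        )
        if self.upsample == 4:
            w.upsampled = Waveform(
                fs=4 * self.fs, start=int(self.start4[element, point]),
                data=self.data4[element, point],
            )
        return w

    def delayed(self, element: int, point: int, delay: float, mode: DelayMode) -> Waveform:
        if mode == "analytic":
            raise ValueError(
                "the cache stores samples only; use transient_pressure for "
                "analytic delays"
            )
        return delayed_copy(self.get(element, point), delay, mode)


def build_intermediate_cache(
    array: TransducerArray,
    points: np.ndarray,
    excitation: Excitation,
    medium: Medium,
    fs: float,
    quad: QuadratureSet,
    upsample: int = 1,
) -> IntermediateCache:
    """Precompute undelayed intermediates for all (element, scatterer)
    pairs.  With ``upsample=4`` the bank is additionally evaluated at
    4*fs (directly, not by interpolation) to support the upsampled
    shifting mode."""
    if upsample not in (1, 4):
        raise ValueError("upsample must be 1 or 4")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    data, start = _bank(array.positions, points, excitation, medium, fs, quad)
    cache = IntermediateCache(fs=fs, data=data, start=start, upsample=upsample)
    if upsample == 4:
        data4, start4 = _bank(array.positions, points, excitation, medium, 4 * fs, quad)
        cache.data4, cache.start4 = data4, start4
    return cache
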