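"""HDF5 and image output for RF datasets, beamformed frames, and
velocity maps.

RF layout: ``/rf/<event label>/data`` (float32, channel x time) with
attrs ``fs``, ``t0``, ``delays``, ``delay_offset``, ``apodization``,
``tx_indices``, and ``angle_deg`` where applicable; dataset-level attrs
record the array geometry, medium, and excitations so a dataset can be
re-loaded without its config.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .beamforming import BeamformingGrid, BModeImage
from .doppler import VelocityMap
from .geometry import (
    DelayVector,
    Excitation,
    Medium,
    TimeGrid,
    build_linear_array,
)
from .rf import RFDataSet, TransmitEvent

__all__ = [
    "write_rf",
    "read_rf",
    "write_velocity",
    "read_velocity",
    "save_bmode_png",
    "save_velocity_overlay_png",
]


def write_rf(path, rf: RFDataSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("rf")
        f.attrs["fs"] = rf.fs
        f.attrs["t0"] = rf.grid.t0
        f.attrs["n_samples"] = rf.grid.n_samples
        f.attrs["mode"] = rf.mode
        f.attrs["n_elements"] = rf.array.n_elements
        f.attrs["width"] = rf.array.width
        f.attrs["height"] = rf.array.height
        f.attrs["kerf"] = rf.array.kerf
        f.attrs["sound_speed"] = rf.medium.sound_speed
        f.attrs["density"] = rf.medium.density
        f.attrs["tx_f0"] = rf.excitation_tx.f0
        f.attrs["tx_n_cycles"] = rf.excitation_tx.n_cycles
        f.attrs["rx_f0"] = rf.excitation_rx.f0
        f.attrs["rx_n_cycles"] = rf.excitation_rx.n_cycles
        for k, (ev, data) in enumerate(zip(rf.events, rf.data)):
            ds = g.create_group(f"{k:04d}_{ev.label}")
            ds.create_dataset("data", data=data.astype(np.float32))
            ds.attrs["label"] = ev.label
            ds.attrs["tx_indices"] = ev.tx_indices
            ds.attrs["delays"] = ev.delays.delays
            ds.attrs["delay_offset"] = ev.delays.offset
            ds.attrs["apodization"] = ev.apodization
            if ev.angle_deg is not None:
                ds.attrs["angle_deg"] = ev.angle_deg
            if ev.ref_position is not None:
                ds.attrs["ref_position"] = ev.ref_position
            if ev.aline_x is not None:
                ds.attrs["aline_x"] = ev.aline_x


def read_rf(path) -> RFDataSet:
    with h5py.File(path, "r") as f:
        array = build_linear_array(
            int(f.attrs["n_elements"]), float(f.attrs["width"]),
            float(f.attrs["height"]), float(f.attrs["kerf"]),
        )
        medium = Medium(
            sound_speed=float(f.attrs["sound_speed"]),
            density=float(f.attrs["density"]),
        )
        grid = TimeGrid(
            fs=float(f.attrs["fs"]), t0=float(f.attrs["t0"]),
            n_samples=int(f.attrs["n_samples"]),
        )
        exc_tx = Excitation(
            f0=float(f.attrs["tx_f0"]), n_cycles=float(f.attrs["tx_n_cycles"])
        )
        exc_rx = Excitation(
            f0=float(f.attrs["rx_f0"]), n_cycles=float(f.attrs["rx_n_cycles"])
        )
        events, data = [], []
        for name in sorted(f["rf"].keys()):
            ds = f["rf"][name]
            events.append(
                TransmitEvent(
                    tx_indices=np.asarray(ds.attrs["tx_indices"]),
                    delays=DelayVector(
                        delays=np.asarray(ds.attrs["delays"]),
                        offset=float(ds.attrs["delay_offset"]),
                    ),
                    apodization=np.asarray(ds.attrs["apodization"]),
                    label=str(ds.attrs["label"]),
                    angle_deg=(
                        float(ds.attrs["angle_deg"])
                        if "angle_deg" in ds.attrs
                        else None
                    ),
                    ref_position=(
                        np.asarray(ds.attrs["ref_position"])
                        if "ref_position" in ds.attrs
                        else None
                    ),
                    aline_x=(
                        float(ds.attrs["aline_x"])
                        if "aline_x" in ds.attrs
                        else None
                    ),
                )
            )
            data.append(np.asarray(ds["data"], dtype=float))
        return RFDataSet(
            events=events, data=data, grid=grid, array=array, medium=medium,
            excitation_tx=exc_tx, excitation_rx=exc_rx,
            mode=str(f.attrs["mode"]),
        )


def write_velocity(path, vmap: VelocityMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=vmap.v.astype(np.float32))
        f.create_dataset("mask", data=vmap.valid)
        f.attrs["nyquist"] = vmap.nyquist
        f.attrs["x"] = vmap.grid.x
        f.attrs["z"] = vmap.grid.z
        f.attrs["f_number"] = vmap.grid.f_number


def read_velocity(path) -> VelocityMap:
    with h5py.File(path, "r") as f:
        grid = BeamformingGrid(
            x=np.asarray(f.attrs["x"]), z=np.asarray(f.attrs["z"]),
            f_number=float(f.attrs["f_number"]),
        )
        return VelocityMap(
            v=np.asarray(f["velocity"], dtype=float),
            valid=np.asarray(f["mask"], dtype=bool),
            nyquist=float(f.attrs["nyquist"]),
            grid=grid,
        )


def save_bmode_png(path, image: BModeImage) -> None:
    """Write the log-compressed image as an 8-bit grayscale PNG
    (0 dB -> 255, -dynamic_range dB -> 0)."""
    import imageio.v3 as iio

    u8 = np.clip(
        (image.db + image.dynamic_range) / image.dynamic_range * 255.0,
        0, 255,
    ).astype(np.uint8)
    iio.imwrite(Path(path), u8)


def save_velocity_overlay_png(path, vmap: VelocityMap,
                              bmode: BModeImage | None = None) -> None:
    """Color-flow overlay: velocity (red toward / blue away) over an
    optional grayscale B-mode background."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ext = [
        vmap.grid.x[0] * 1e3, vmap.grid.x[-1] * 1e3,
        vmap.grid.z[-1] * 1e3, vmap.grid.z[0] * 1e3,
    ]
    fig, ax = plt.subplots(figsize=(6, 5))
    if bmode is not None:
        ax.imshow(bmode.db, cmap="gray", extent=ext, aspect="auto",
                  vmin=-bmode.dynamic_range, vmax=0)
    v = np.ma.masked_where(~vmap.valid, vmap.v)
    im = ax.imshow(v, cmap="RdBu_r", extent=ext, aspect="auto",
                   vmin=-vmap.nyquist, vmax=vmap.nyquist)
    fig.colorbar(im, ax=ax, label="velocity (m/s, + toward array)")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    fig.savefig(Path(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
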