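"""File formats: YAML configs, HDF5 channel frames, NIfTI volumes, CSV tables.

Channel data (RF traces and averaged frames) go to HDF5 with sampling
metadata as attributes; reconstructed and planned volumes go to NIfTI
with the grid spacing/origin in the affine; delivery timelines go to
CSV.  All spatial metadata is millimetres, matching the in-memory
convention.
"""

from __future__ import annotations

import csv

import h5py
import nibabel as nib
import numpy as np
import yaml

from .acquisition import ChannelFrame
from .forward import ChannelSignals
from .geometry import ArrayGeometry, Grid3D, Medium, MEDIUM_PRESETS, RadiationPulse
from .plans import DoseVolume
from .recon import ReconVolume


def save_frames(path, frames: list[ChannelSignals]) -> None:
    """Write frames to HDF5: groups ``/frames/0000, 0001, ...``."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("frames")
        for i, frame in enumerate(frames):
            g = grp.create_group(f"{i:04d}")
            g.create_dataset("signals", data=frame.data, compression="gzip")
            g.attrs["dt_us"] = frame.dt
            g.attrs["t0_us"] = frame.t0
            if isinstance(frame, ChannelFrame):
                g.attrs["frame_time_s"] = frame.frame_time
                g.attrs["pulses_averaged"] = frame.pulses_averaged


def load_frames(path) -> list[ChannelSignals]:
    frames = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["frames"].keys()):
            g = f["frames"][key]
            kwargs = dict(
                data=g["signals"][()],
                dt=float(g.attrs["dt_us"]),
                t0=float(g.attrs["t0_us"]),
            )
            if "frame_time_s" in g.attrs:
                frames.append(ChannelFrame(
                    frame_time=float(g.attrs["frame_time_s"]),
                    pulses_averaged=int(g.attrs["pulses_averaged"]),
                    **kwargs,
                ))
            else:
                frames.append(ChannelSignals(**kwargs))
    return frames


def _affine(grid: Grid3D) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_volume(path, volume: ReconVolume | DoseVolume) -> None:
    """Write a gridded volume as NIfTI (spacing/origin in the affine)."""
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.grid)), str(path))


def load_volume(path) -> ReconVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj, dtype=np.float64)
    grid = Grid3D(shape=data.shape, spacing=spacing, origin=origin)
    return ReconVolume(grid=grid, values=data)


def save_timeline(path, timeline) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["beam_index", "start_s", "stop_s", "n_pulses"])
        w.writerows(timeline)


def load_config(path) -> dict:
    """Read a YAML experiment config: array/medium/pulse/grid sections.

    Returns a dict of constructed objects for the sections present;
    unknown keys in each section raise, missing sections fall back to
    defaults.  ``medium`` may be a preset name or explicit parameters.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    out = {}
    if "array" in raw:
        out["array"] = ArrayGeometry(**raw["array"])
    if "medium" in raw:
        m = raw["medium"]
        out["medium"] = MEDIUM_PRESETS[m] if isinstance(m, str) else Medium(**m)
    if "pulse" in raw:
        out["pulse"] = RadiationPulse(**raw["pulse"])
    if "grid" in raw:
        g = raw["grid"]
        out["grid"] = Grid3D(
            shape=tuple(g["shape"]),
            spacing=tuple(g["spacing"]),
            origin=tuple(g["origin"]),
        )
    return out
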