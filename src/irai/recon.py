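"""Volumetric delay-and-sum reconstruction and envelope detection.

Delay-and-sum (DAS) back-projects each element's RF trace to every
voxel at the one-way acoustic time of flight and sums coherently with
uniform weights.  The signed DAS volume is RF-like along the array
normal (z); the non-negative relative-dose image is its per-column
analytic-signal magnitude (envelope along z), normalised to its own
maximum.  Temporal accumulation re-uses DAS linearity: frames are
summed coherently before a single back-projection per snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numba
import numpy as np
from scipy.signal import hilbert

from .forward import ChannelSignals
from .geometry import ArrayGeometry, Grid3D, Medium

logger = logging.getLogger(__name__)

#: back-projection delay offset, us: aligns reconstruction to the centroid
#: of the (causal, ~4 us square) radiation pulse
DEFAULT_DELAY_OFFSET = 2.0


@dataclass
class ReconVolume:
    """Reconstructed volume on a regular grid.

    ``values`` are signed right after DAS and non-negative after
    envelope detection; ``normalization`` records whether the volume has
    been scaled to unit maximum.
    """

    grid: Grid3D
    values: np.ndarray
    normalization: str = "none"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("volume shape does not match grid")


@numba.njit(cache=True, fastmath=True)
def _das_kernel(data, centers, vox, inv_c_dt, t0_dt, n_samples, out):
    # pragma: no cover - numba kernel, exercised via das_reconstruct
    n_elem = centers.shape[0]
    n_vox = vox.shape[0]
    for v in range(n_vox):
        vx = vox[v, 0]
        vy = vox[v, 1]
        vz = vox[v, 2]
        acc = 0.0
        for e in range(n_elem):
            dx = vx - centers[e, 0]
            dy = vy - centers[e, 1]
            dz = vz - centers[e, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            s = r * inv_c_dt - t0_dt  # fractional sample index
            i = int(np.floor(s))
            if 0 <= i < n_samples - 1:
                w = s - i
                acc += (1.0 - w) * data[e, i] + w * data[e, i + 1]
        out[v] = acc


def das_reconstruct(
    frames: ChannelSignals | Sequence[ChannelSignals],
    geom: ArrayGeometry,
    grid: Grid3D,
    medium: Medium,
    delay_offset: float = DEFAULT_DELAY_OFFSET,
) -> ReconVolume:
    """Signed delay-and-sum back-projection of one or more frames.

    Multiple frames are summed coherently (channel-wise) before
    back-projection — DAS is linear in the channel data, so this equals
    the sum of per-frame reconstructions.  ``delay_offset`` (us) is
    added to every time of flight to align the image with the centroid
    of the causal radiation pulse.  Delays falling outside the record
    contribute zero (logged once).
    """
    if isinstance(frames, ChannelSignals):
        frame_list = [frames]
    else:
        frame_list = list(frames)
    if not frame_list:
        raise ValueError("no frames to reconstruct")
    first = frame_list[0]
    data = np.zeros_like(first.data)
    for f in frame_list:
        if f.dt != first.dt or f.t0 != first.t0 or f.data.shape != first.data.shape:
            raise ValueError("frames must share sampling and shape")
        data += f.data
    if data.shape[0] != geom.n_elements:
        raise ValueError("channel count does not match array geometry")

    c = medium.c_mm_us
    vox = grid.voxel_centers()
    r_max = np.linalg.norm(
        np.abs(vox).max(axis=0)
        + np.array([geom.aperture[0] / 2, geom.aperture[1] / 2, 0.0])
    )
    if r_max / c - first.t0 + delay_offset > (first.n_samples - 1) * first.dt:
        logger.info("some voxel-element delays fall outside the record; "
                    "those contributions are zero")

    out = np.empty(vox.shape[0])
    _das_kernel(
        data,
        geom.element_centers,
        vox,
        1.0 / (c * first.dt),
        (first.t0 - delay_offset) / first.dt,
        first.n_samples,
        out,
    )
    return ReconVolume(
        grid=grid,
        values=out.reshape(grid.shape),
        normalization="none",
        provenance={"n_frames": len(frame_list)},
    )


def envelope_normal(volume: ReconVolume) -> ReconVolume:
    """Per-(x, y) column analytic-signal magnitude along the array normal z."""
    if volume.grid.shape[2] < 2:
        raise ValueError("envelope needs more than one sample along z")
    env = np.abs(hilbert(volume.values, axis=2))
    return ReconVolume(
        grid=volume.grid, values=env, normalization="none",
        provenance=dict(volume.provenance),
    )


def normalize_max1(volume: ReconVolume) -> ReconVolume:
    """Scale to unit maximum (identity on all-zero volumes)."""
    peak = volume.values.max()
    values = volume.values / peak if peak > 0 else volume.values.copy()
    return ReconVolume(
        grid=volume.grid, values=values, normalization="max1",
        provenance=dict(volume.provenance),
    )


def reconstruct(
    frames: ChannelSignals | Sequence[ChannelSignals],
    geom: ArrayGeometry,
    grid: Grid3D,
    medium: Medium,
    delay_offset: float = DEFAULT_DELAY_OFFSET,
    normalize: bool = True,
) -> ReconVolume:
    """DAS + envelope (+ optional max-1 normalisation) in one call."""
    vol = envelope_normal(
        das_reconstruct(frames, geom, grid, medium, delay_offset=delay_offset)
    )
    return normalize_max1(vol) if normalize else vol


def accumulate(
    frames: Sequence[ChannelSignals],
    geom: ArrayGeometry,
    grid: Grid3D,
    medium: Medium,
    mode: str = "cumulative",
    every: int = 1,
    delay_offset: float = DEFAULT_DELAY_OFFSET,
) -> list[ReconVolume]:
    """Temporal dose snapshots from a time-ordered frame stream.

    ``cumulative`` reconstructs frames ``1..k`` coherently at every
    ``every``-th frame (the dose accumulated so far); ``difference``
    reconstructs only the frames since the previous snapshot (the dose
    delivered between consecutive time points).  All snapshots are
    envelope-detected and normalised jointly to the global maximum, so
    cumulative sequences are visually monotone.
    """
    if not frames:
        raise ValueError("empty frame list")
    if mode not in ("cumulative", "difference"):
        raise ValueError(f"unknown accumulation mode {mode!r}")
    marks = list(range(every - 1, len(frames), every))
    if marks and marks[-1] != len(frames) - 1:
        marks.append(len(frames) - 1)
    snaps = []
    prev = 0
    for k in marks:
        chunk = frames[: k + 1] if mode == "cumulative" else frames[prev : k + 1]
        vol = envelope_normal(
            das_reconstruct(chunk, geom, grid, medium, delay_offset=delay_offset)
        )
        vol.provenance.update({"last_frame": k, "mode": mode})
        snaps.append(vol)
        prev = k + 1
    peak = max(v.values.max() for v in snaps)
    if peak > 0:
        for v in snaps:
            v.values /= peak
            v.normalization = "max1-sequence"
    return snaps
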