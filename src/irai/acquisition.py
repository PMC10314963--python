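"""Acquisition chain: multiplexed readout, frame assembly, averaging.

The 1,024-element array is read through a 4:1 multiplexer: each
accelerator trigger digitises one fixed group of 256 elements, so a
full-array acquisition takes four consecutive pulses.  Displayed frames
average 25 full acquisitions (100 pulses); each element is therefore
averaged over exactly 25 reads.  Within a frame the active beam may
change — every pulse uses the beam scheduled at its timestamp, which is
what makes per-frame images of "dose delivered since the last time
point" meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward import ChannelSignals, dose_to_pressure, simulate_channels
from .geometry import ArrayGeometry, Grid3D, Medium, RadiationPulse
from .plans import DEFAULT_PRF_HZ, PlanSpec, rectangular_beam_dose

logger = logging.getLogger(__name__)

DEFAULT_N_GROUPS = 4
DEFAULT_ACQUISITIONS_PER_FRAME = 25


@dataclass
class ChannelFrame(ChannelSignals):
    """One averaged multiplexed frame.

    ``pulses_averaged`` counts all pulses in the frame window
    (``n_groups * acquisitions``); each individual element is averaged
    over ``pulses_averaged / n_groups`` reads.  ``group_pulses`` maps
    each multiplexer group to the global pulse indices it digitised.
    """

    frame_time: float = 0.0  # s, centre of the averaging window
    pulses_averaged: int = 0
    group_pulses: dict = field(default_factory=dict)


def group_schedule(n_elements: int, n_groups: int = DEFAULT_N_GROUPS) -> np.ndarray:
    """Deterministic element-to-group map: contiguous blocks.

    Returns an integer array of length ``n_elements`` with values in
    ``[0, n_groups)``; groups partition the elements into equal blocks.
    """
    if n_elements % n_groups != 0:
        raise ValueError(
            f"{n_elements} elements not divisible into {n_groups} groups"
        )
    block = n_elements // n_groups
    return np.repeat(np.arange(n_groups), block)


def expand_pulse_beams(
    timeline: list[tuple[int, float, float, int]]
) -> np.ndarray:
    """Beam index active at each global pulse (pulses fire on the PRF clock)."""
    total = sum(n for (_, _, _, n) in timeline)
    beam_of_pulse = np.empty(total, dtype=np.int64)
    pos = 0
    for beam_idx, _start, _stop, n in timeline:
        beam_of_pulse[pos : pos + n] = beam_idx
        pos += n
    return beam_of_pulse


def acquire_frames(
    timeline: list[tuple[int, float, float, int]],
    pulse_signals: list[ChannelSignals],
    acquisitions_per_frame: int = DEFAULT_ACQUISITIONS_PER_FRAME,
    n_groups: int = DEFAULT_N_GROUPS,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
    prf_hz: float = DEFAULT_PRF_HZ,
    noise_mode: str = "averaged",
) -> list[ChannelFrame]:
    """Assemble averaged multiplexed frames from per-beam single-pulse signals.

    ``pulse_signals[b]`` is the clean signal of one pulse of beam ``b``
    (at the per-pulse dose of that beam).  Each frame spans
    ``n_groups * acquisitions_per_frame`` pulses; element group ``g``
    is read on pulses with index ``g`` modulo ``n_groups`` and averaged
    over its ``acquisitions_per_frame`` reads.  Gaussian read noise of
    s.d. ``noise_sigma`` is added per digitised sample:
    ``noise_mode='per_pulse'`` draws it read by read and averages
    (literal chain), ``'averaged'`` draws the statistically identical
    averaged noise ``N(0, sigma / sqrt(acquisitions))`` directly (one
    draw per element sample per frame; the default, much faster).
    Trailing pulses short of a full frame are dropped (logged).
    """
    if not timeline:
        raise ValueError("empty delivery timeline")
    if acquisitions_per_frame < 1:
        raise ValueError("acquisitions_per_frame must be >= 1")
    if noise_mode not in ("averaged", "per_pulse"):
        raise ValueError(f"unknown noise mode {noise_mode!r}")
    ref = pulse_signals[0]
    n_elements, n_samples = ref.data.shape
    groups = group_schedule(n_elements, n_groups)
    beam_of_pulse = expand_pulse_beams(timeline)
    pulses_per_frame = n_groups * acquisitions_per_frame
    n_frames = len(beam_of_pulse) // pulses_per_frame
    if n_frames == 0:
        raise ValueError(
            f"only {len(beam_of_pulse)} pulses scheduled; a full frame "
            f"needs {pulses_per_frame}"
        )
    dropped = len(beam_of_pulse) - n_frames * pulses_per_frame
    if dropped:
        logger.info("dropping %d trailing pulses (partial frame)", dropped)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = np.stack([s.data for s in pulse_signals])  # (n_beams, elem, samp)
    frames: list[ChannelFrame] = []
    for f in range(n_frames):
        p0 = f * pulses_per_frame
        frame_pulses = np.arange(p0, p0 + pulses_per_frame)
        data = np.empty((n_elements, n_samples))
        group_pulses = {}
        for g in range(n_groups):
            reads = frame_pulses[frame_pulses % n_groups == g]
            group_pulses[g] = reads
            counts = np.bincount(beam_of_pulse[reads], minlength=clean.shape[0])
            mean_clean = np.tensordot(
                counts / acquisitions_per_frame, clean, axes=(0, 0)
            )
            sel = groups == g
            data[sel] = mean_clean[sel]
            if noise_sigma > 0:
                if noise_mode == "per_pulse":
                    noise = rng.normal(
                        0.0, noise_sigma, size=(len(reads), sel.sum(), n_samples)
                    ).mean(axis=0)
                else:
                    noise = rng.normal(
                        0.0,
                        noise_sigma / np.sqrt(acquisitions_per_frame),
                        size=(sel.sum(), n_samples),
                    )
                data[sel] += noise
        frames.append(
            ChannelFrame(
                data=data,
                dt=ref.dt,
                t0=ref.t0,
                frame_time=(p0 + pulses_per_frame / 2.0) / prf_hz,
                pulses_averaged=pulses_per_frame,
                group_pulses=group_pulses,
            )
        )
    return frames


def beam_pulse_signals(
    plan: PlanSpec,
    timeline: list[tuple[int, float, float, int]],
    grid: Grid3D,
    geom: ArrayGeometry,
    medium: Medium,
    pulse: RadiationPulse,
    **forward_kwargs,
) -> list[ChannelSignals]:
    """Clean single-pulse signals for every beam of a plan.

    Beam ``b`` deposits ``1 / n_pulses_b`` of its total dose per pulse,
    so the coherent sum over the whole timeline reproduces the signals
    of the static composite dose exactly.
    """
    signals = []
    for (beam_idx, _s, _e, n_pulses) in timeline:
        beam = plan.beams[beam_idx]
        dose = rectangular_beam_dose(
            beam, grid, isocenter=plan.isocenter,
            normalize=beam.aperture is None,
        )
        per_pulse = dose.values / max(n_pulses, 1)
        p0 = dose_to_pressure(
            type(dose)(grid=grid, values=per_pulse), medium
        )
        signals.append(
            simulate_channels(p0, geom, medium, pulse, **forward_kwargs)
        )
    return signals
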