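"""Transducer array, propagation medium, radiation pulse and imaging grid.

The imaging geometry used throughout the package: a planar 2D matrix
array lies in the ``z = 0`` plane, centred on the origin, receiving on
+z.  The +z axis is the array normal ("axial" direction); x and y are
lateral.  All lengths are millimetres and all times are microseconds
internally; speeds are therefore mm/us (1540 m/s == 1.54 mm/us).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MM_PER_US_PER_M_PER_S = 1e-3  # m/s -> mm/us

#: full width at half maximum of a Gaussian, in units of sigma
FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class ArrayGeometry:
    """Planar 2D matrix receive array on the ``z = 0`` plane.

    Parameters
    ----------
    n_x, n_y:
        Element counts per row / column.
    element_size:
        Square element side, mm.
    kerf:
        Gap between neighbouring elements, mm.  Pitch is
        ``element_size + kerf``.
    center_frequency:
        Receive-band centre frequency, MHz.
    fractional_bandwidth:
        Full fractional bandwidth of the receive band (width between the
        half-power points of the power spectrum divided by the centre
        frequency).
    """

    n_x: int = 32
    n_y: int = 32
    element_size: float = 3.45
    kerf: float = 0.2
    center_frequency: float = 0.35
    fractional_bandwidth: float = 0.5

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("element counts must be >= 1")
        if self.element_size <= 0 or self.kerf < 0:
            raise ValueError("element size must be > 0 and kerf >= 0")
        if self.center_frequency <= 0:
            raise ValueError("center frequency must be > 0")
        if self.fractional_bandwidth <= 0:
            raise ValueError("fractional bandwidth must be > 0")

    @property
    def pitch(self) -> float:
        """Centre-to-centre element spacing, mm."""
        return self.element_size + self.kerf

    @property
    def n_elements(self) -> int:
        return self.n_x * self.n_y

    @property
    def aperture(self) -> tuple[float, float]:
        """Physical aperture side lengths ``n*s + (n-1)*k``, mm."""
        return (
            self.n_x * self.element_size + (self.n_x - 1) * self.kerf,
            self.n_y * self.element_size + (self.n_y - 1) * self.kerf,
        )

    @property
    def element_centers(self) -> np.ndarray:
        """``(n_elements, 3)`` element centres, row-major (y outer, x inner)."""
        xs = (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.pitch
        ys = (np.arange(self.n_y) - (self.n_y - 1) / 2.0) * self.pitch
        gx, gy = np.meshgrid(xs, ys)  # shape (n_y, n_x): y varies along rows
        centers = np.column_stack(
            [gx.ravel(), gy.ravel(), np.zeros(self.n_x * self.n_y)]
        )
        return centers


def build_array(
    n_x: int = 32,
    n_y: int = 32,
    element_size: float = 3.45,
    kerf: float = 0.2,
    f0: float = 0.35,
    bw: float = 0.5,
) -> ArrayGeometry:
    """Construct an :class:`ArrayGeometry` (thin validated constructor)."""
    return ArrayGeometry(
        n_x=n_x,
        n_y=n_y,
        element_size=element_size,
        kerf=kerf,
        center_frequency=f0,
        fractional_bandwidth=bw,
    )


@dataclass(frozen=True)
class Medium:
    """Homogeneous acoustic propagation / thermoacoustic generation medium.

    ``grueneisen`` (dimensionless) converts absorbed energy density to
    initial pressure: ``p0 = grueneisen * density * dose`` with dose in
    Gy (J/kg), giving p0 in Pa.
    """

    speed_of_sound: float  # m/s
    density: float  # kg/m^3
    grueneisen: float  # dimensionless

    def __post_init__(self) -> None:
        if min(self.speed_of_sound, self.density, self.grueneisen) <= 0:
            raise ValueError("medium parameters must be strictly positive")

    @property
    def c_mm_us(self) -> float:
        """Speed of sound in internal units, mm/us."""
        return self.speed_of_sound * MM_PER_US_PER_M_PER_S


# Presets.  Lard approximates the fat-like phantom material used for
# bench calibration (low sound speed, high Grueneisen — fat converts
# heat to pressure efficiently); soft tissue is the in-vivo stand-in.
# These scale factors cancel in all normalised (max-1) images.
LARD = Medium(speed_of_sound=1440.0, density=920.0, grueneisen=0.9)
SOFT_TISSUE = Medium(speed_of_sound=1540.0, density=1000.0, grueneisen=0.2)

MEDIUM_PRESETS = {"lard": LARD, "soft_tissue": SOFT_TISSUE}


@dataclass(frozen=True)
class RadiationPulse:
    """Temporal profile of one megavoltage accelerator pulse.

    ``duration`` is the full width of a square pulse, or the FWHM of a
    gaussian pulse, in microseconds.  ``repetition_period`` (ms) is pure
    acquisition bookkeeping (pulse repetition frequency of the
    accelerator), not part of the waveform.
    """

    duration: float = 4.0
    shape: str = "square"
    repetition_period: float = 1000.0 / 360.0  # ms; 360 Hz default PRF

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be > 0")
        if self.shape not in ("square", "gaussian"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")

    @property
    def prf_hz(self) -> float:
        return 1000.0 / self.repetition_period


def pulse_profile(
    pulse: RadiationPulse, dt: float, n_samples: int | None = None
) -> np.ndarray:
    """Sample the unit-area pulse time profile starting at t = 0.

    Sample ``k`` represents the interval ``[k*dt, (k+1)*dt)``; a square
    pulse therefore has exactly ``duration/dt`` non-zero samples when
    that ratio is an integer, and fractionally weighted boundary samples
    otherwise, so that ``sum(profile) * dt == 1`` for any dt.

    Returns values in 1/us.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt >= pulse.duration:
        raise ValueError(
            f"dt={dt} us undersamples the {pulse.duration} us pulse"
        )
    tau = pulse.duration
    if pulse.shape == "square":
        n = int(np.ceil(tau / dt)) if n_samples is None else n_samples
        k = np.arange(n)
        # overlap of [k dt, (k+1) dt) with [0, tau), as a fraction of dt
        overlap = np.clip((np.minimum((k + 1) * dt, tau) - k * dt) / dt, 0.0, 1.0)
        return overlap / tau
    # gaussian: duration is the FWHM; centre the pulse so that it is
    # causal with negligible truncation (4 sigma lead-in)
    sigma = tau / FWHM_SIGMA
    t_c = 4.0 * sigma
    n = int(np.ceil((t_c + 4.0 * sigma) / dt)) if n_samples is None else n_samples
    t = (np.arange(n) + 0.5) * dt
    prof = np.exp(-0.5 * ((t - t_c) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    return prof


def transducer_impulse_response(
    geometry: ArrayGeometry, dt: float, n_sigmas: float = 4.0
) -> np.ndarray:
    """Zero-phase band-pass receive kernel of the array.

    A Gaussian-modulated cosine at the centre frequency whose magnitude
    spectrum falls to ``sqrt(0.5)`` of its peak at
    ``f0 * (1 +/- bw / 2)`` — i.e. the full width between the
    half-power points of the power spectrum is ``bw * f0``.  The kernel
    is symmetric (zero phase) with unit peak spectral magnitude at f0,
    and has odd length ``2 * ceil(n_sigmas * sigma_t / dt) + 1``.
    """
    f0 = geometry.center_frequency
    bw = geometry.fractional_bandwidth
    if 1.0 / dt < 4.0 * f0:
        raise ValueError(
            f"sampling rate {1.0 / dt:.3f} MHz below 4*f0 = {4 * f0:.3f} MHz"
        )
    # |H(f)| = exp(-(f-f0)^2 / (2 sigma_f^2)); sqrt(0.5) at f0*bw/2 offset
    sigma_f = bw * f0 / (2.0 * np.sqrt(np.log(2.0)))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(n_sigmas * sigma_t / dt))
    t = np.arange(-half, half + 1) * dt
    h = np.exp(-0.5 * (t / sigma_t) ** 2) * np.cos(2.0 * np.pi * f0 * t)
    # unit peak spectral magnitude at f0 (one-sided DTFT evaluated at f0)
    mag = np.abs(np.sum(h * np.exp(-2j * np.pi * f0 * t)) * dt)
    return h / mag


@dataclass(frozen=True)
class Grid3D:
    """Regular voxel lattice, voxel-centre convention, zero-based indices.

    ``origin`` is the position (mm) of the centre of voxel (0, 0, 0);
    axis order of ``shape`` and ``spacing`` is (x, y, z).  The grid must
    lie strictly in front of the array (z > 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError("shape must be three positive voxel counts")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths")
        if self.origin[2] <= 0:
            raise ValueError("grid must lie at z > 0, in front of the array")

    @classmethod
    def from_extent(
        cls,
        x: tuple[float, float],
        y: tuple[float, float],
        z: tuple[float, float],
        spacing: float | tuple[float, float, float],
    ) -> "Grid3D":
        """Build a grid whose voxel centres span the closed extents given."""
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        shape = tuple(
            int(round((hi - lo) / sp)) + 1
            for (lo, hi), sp in zip((x, y, z), spacing)
        )
        origin = (x[0], y[0], z[0])
        return cls(shape=shape, spacing=tuple(spacing), origin=origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis (0=x, 1=y, 2=z), mm."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinate arrays, each of shape ``self.shape``."""
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )

    def voxel_centers(self) -> np.ndarray:
        """All voxel centres as an ``(n_voxels, 3)`` array (C order)."""
        gx, gy, gz = self.meshgrid()
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm^3."""
        return float(np.prod(self.spacing))
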