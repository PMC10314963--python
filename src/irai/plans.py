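"""Synthetic radiotherapy dose volumes and delivery schedules.

Beams are megavoltage photon fields with error-function lateral edges
(penumbra) and exponential depth attenuation.  The gantry rotates about
the x axis, so beam axes stay in the y-z plane — the plane the planar
receive array (z = 0) images best.  Gantry angle 0 points the beam
along -y ("from above"); positive angles rotate the entry point toward
+z.

Composite plans provided:

* a C-shaped target treated with many equally spaced conformal beams
  whose aperture transmissions are synthesized from filtered
  projections of the target (a deliberately simple stand-in for a
  clinical treatment planning system), and
* a four-beam preset with gantry angles 30/40/320/340 degrees, 3 x 3 cm
  fields, scaled to a 5.36 Gy maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .geometry import Grid3D

DEFAULT_PENUMBRA_SIGMA = 2.0  # mm; lateral 20-80% falloff of a 6 MV beam edge
DEFAULT_MU = 0.005  # 1/mm; effective 6 MV depth attenuation in water-like media
DEFAULT_PRF_HZ = 360.0  # accelerator pulse repetition frequency
GY_PER_MU = 0.01  # 1 MU == 1 cGy at the composite maximum (bookkeeping scale)


@dataclass(frozen=True)
class BeamSpec:
    """One static photon beam.

    ``field_size = (width_x, width_t)`` is the field extent (mm between
    the 50% edge levels) along x and along the in-plane transverse axis
    (which coincides with z at gantry angle 0).  ``aperture``, when
    present, replaces the transverse error-function edge pair with an
    arbitrary sampled transmission profile ``(t_mm, transmission)`` —
    used by conformal composite plans.
    """

    field_size: tuple[float, float]
    gantry_angle: float = 0.0
    weight: float = 1.0
    penumbra_sigma: float = DEFAULT_PENUMBRA_SIGMA
    attenuation_mu: float = DEFAULT_MU
    offset_t: float = 0.0
    aperture: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ValueError("field sizes must be > 0")
        if self.weight < 0:
            raise ValueError("beam weight must be >= 0")


@dataclass(frozen=True)
class PlanSpec:
    """Ordered beam list plus the delivery timeline bookkeeping."""

    beams: tuple[BeamSpec, ...]
    isocenter: tuple[float, float, float]
    max_dose: float  # Gy at the composite maximum
    total_duration: float  # s
    dose_rate: float = 1400.0  # monitor units per minute
    gy_per_mu: float = GY_PER_MU

    def __post_init__(self) -> None:
        if len(self.beams) < 1:
            raise ValueError("a plan needs at least one beam")
        if self.total_duration <= 0 or self.dose_rate <= 0:
            raise ValueError("duration and dose rate must be > 0")


@dataclass
class DoseVolume:
    """3D absorbed dose (Gy) on a regular grid."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("dose array shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose must be finite")
        if self.values.min() < 0:
            raise ValueError("dose must be non-negative")


def beam_axes(gantry_angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit beam direction and in-plane transverse axis for a gantry angle.

    Returns ``(d, t_hat)``: ``d`` is the direction of travel
    (``(0, -1, 0)`` at angle 0), ``t_hat`` completes the right-handed
    frame ``(x_hat, t_hat, d)`` and equals ``+z`` at angle 0.
    """
    g = np.deg2rad(gantry_angle_deg)
    d = np.array([0.0, -np.cos(g), -np.sin(g)])
    t_hat = np.array([0.0, -np.sin(g), np.cos(g)])
    return d, t_hat


def _edge_pair(q: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Error-function field edge pair: ~1 inside ``|q| < half_width``, 0.5 at the edges."""
    if sigma <= 0:
        return ((q > -half_width) & (q < half_width)).astype(np.float64)
    s = np.sqrt(2.0) * sigma
    return 0.5 * (erf((q + half_width) / s) - erf((q - half_width) / s))


def _default_isocenter(grid: Grid3D) -> np.ndarray:
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    return (lo + hi) / 2.0


def rectangular_beam_dose(
    beam: BeamSpec,
    grid: Grid3D,
    isocenter: tuple[float, float, float] | None = None,
    normalize: bool = True,
) -> DoseVolume:
    """Analytic dose of one beam evaluated on a grid.

    Separable profile in beam-local coordinates: erf edge pairs across
    the field (or the beam's sampled aperture transmission), times
    ``exp(-mu * s)`` with ``s`` the downstream distance from the
    isocenter plane.  With ``normalize`` the volume maximum is scaled to
    ``beam.weight`` (the default for stand-alone fields); composite
    plans pass ``normalize=False`` to keep beams on a common absolute
    scale.
    """
    iso = _default_isocenter(grid) if isocenter is None else np.asarray(isocenter, float)
    d, t_hat = beam_axes(beam.gantry_angle)
    gx, gy, gz = grid.meshgrid()
    rx = gx - iso[0]
    ry = gy - iso[1]
    rz = gz - iso[2]
    s = ry * d[1] + rz * d[2]
    t = ry * t_hat[1] + rz * t_hat[2] - beam.offset_t

    wx, wt = beam.field_size
    profile_x = _edge_pair(rx, wx / 2.0, beam.penumbra_sigma)
    if beam.aperture is None:
        profile_t = _edge_pair(t, wt / 2.0, beam.penumbra_sigma)
    else:
        t_mm, transmission = beam.aperture
        profile_t = np.interp(t, t_mm, transmission, left=0.0, right=0.0)
    values = profile_x * profile_t * np.exp(-beam.attenuation_mu * s)

    peak = values.max()
    if peak <= 0:
        warnings.warn("beam does not intersect the grid; returning zero dose")
        return DoseVolume(grid=grid, values=np.zeros(grid.shape))
    if normalize:
        values *= beam.weight / peak
    else:
        values *= beam.weight
    return DoseVolume(grid=grid, values=values)


def composite_dose(
    plan: PlanSpec, grid: Grid3D, normalize_beams: bool = False
) -> DoseVolume:
    """Sum of all beam doses of a plan on one grid (absolute beam scales)."""
    total = np.zeros(grid.shape)
    for beam in plan.beams:
        total += rectangular_beam_dose(
            beam, grid, isocenter=plan.isocenter, normalize=normalize_beams
        ).values
    return DoseVolume(grid=grid, values=total)


# ---------------------------------------------------------------------------
# C-shaped conformal plan
# ---------------------------------------------------------------------------


def cshape_target(
    grid: Grid3D,
    isocenter: tuple[float, float, float],
    outer_radius: float = 25.0,
    inner_radius: float = 12.5,
    gap_angle: float = 90.0,
    thickness: float = 20.0,
    penumbra_sigma: float = DEFAULT_PENUMBRA_SIGMA,
    max_dose: float = 7.0,
) -> DoseVolume:
    """Planned C-shaped dose: a smoothed annular sector in the y-z plane.

    The annulus lives in the y-z plane (extruded ``thickness`` mm along
    x); the gap of ``gap_angle`` degrees opens toward +y.  The binary
    target is smoothed by an isotropic Gaussian of ``penumbra_sigma``
    and scaled to ``max_dose``.
    """
    if inner_radius >= outer_radius:
        raise ValueError("inner radius must be smaller than outer radius")
    iso = np.asarray(isocenter, float)
    gx, gy, gz = grid.meshgrid()
    ry, rz = gy - iso[1], gz - iso[2]
    rho = np.hypot(ry, rz)
    # polar angle measured from +y (the gap direction)
    phi = np.arctan2(rz, ry)
    half_gap = np.deg2rad(gap_angle) / 2.0
    mask = (
        (rho >= inner_radius)
        & (rho <= outer_radius)
        & (np.abs(phi) >= half_gap)
        & (np.abs(gx - iso[0]) <= thickness / 2.0)
    ).astype(np.float64)
    if mask.max() > 0 and penumbra_sigma > 0:
        mask = ndimage.gaussian_filter(
            mask, sigma=[penumbra_sigma / sp for sp in grid.spacing]
        )
    peak = mask.max()
    values = mask * (max_dose / peak) if peak > 0 else mask
    return DoseVolume(grid=grid, values=values)


def _annular_sector_indicator(
    y: np.ndarray,
    z: np.ndarray,
    outer: float,
    inner: float,
    gap_angle: float,
) -> np.ndarray:
    rho = np.hypot(y, z)
    phi = np.arctan2(z, y)
    half_gap = np.deg2rad(gap_angle) / 2.0
    return (
        (rho >= inner) & (rho <= outer) & (np.abs(phi) >= half_gap)
    ).astype(np.float64)


def _synthesize_apertures(
    outer: float,
    inner: float,
    gap_angle: float,
    angles: np.ndarray,
    mu: float,
    penumbra_sigma: float,
    t_step: float = 1.0,
    plane_step: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beam aperture fluences conforming the composite to the C target.

    A minimal treatment-planning stand-in: on the in-plane (y, z) grid,
    solve the non-negative least-squares problem
    ``min ||sum_k A_k f_k - target||``, where ``A_k`` extrudes beam k's
    transverse fluence ``f_k >= 0`` along its direction with exponential
    depth attenuation.  Fluence support is restricted to the beam's-eye-
    view silhouette of the target (external beams cannot deliver outside
    it anyway).  Negative fluence being unphysical, the composite
    necessarily retains some dose in the cold core and gap — exactly as
    clinical plans for ring-shaped targets do.

    Returns ``(t_mm, fluences)`` with fluences of shape
    ``(n_beams, t_mm.size)``.
    """
    from scipy import sparse
    from scipy.optimize import lsq_linear

    half_span = outer * 1.6
    t_grid = np.arange(-half_span, half_span + t_step, t_step)
    coords = np.arange(-half_span, half_span + plane_step, plane_step)
    yy, zz = np.meshgrid(coords, coords, indexing="ij")
    target = _annular_sector_indicator(yy, zz, outer, inner, gap_angle)
    if penumbra_sigma > 0:
        target = ndimage.gaussian_filter(target, penumbra_sigma / plane_step)

    n_t = t_grid.size
    rows, cols, vals = [], [], []
    supports = []
    binary = _annular_sector_indicator(yy, zz, outer, inner, gap_angle)
    for k, ang in enumerate(angles):
        d, t_hat = beam_axes(ang)
        s = yy * d[1] + zz * d[2]
        t = yy * t_hat[1] + zz * t_hat[2]
        ti = np.clip(np.round((t - t_grid[0]) / t_step).astype(int), 0, n_t - 1)
        att = np.exp(-mu * s)
        rows.append(np.arange(target.size))
        cols.append(k * n_t + ti.ravel())
        vals.append(att.ravel())
        proj = np.zeros(n_t)
        np.add.at(proj, ti.ravel(), binary.ravel())
        supports.append(ndimage.binary_dilation(proj > 0, iterations=2))
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(target.size, len(angles) * n_t),
    )
    keep = np.flatnonzero(np.concatenate(supports))
    res = lsq_linear(
        A[:, keep], target.ravel(), bounds=(0.0, np.inf), tol=1e-9, max_iter=100
    )
    fluence = np.zeros(len(angles) * n_t)
    fluence[keep] = np.clip(res.x, 0.0, None)
    return t_grid, fluence.reshape(len(angles), n_t)


def cshape_plan(
    grid: Grid3D,
    outer_radius: float = 25.0,
    inner_radius: float = 12.5,
    gap_angle: float = 90.0,
    n_beams: int = 23,
    isocenter: tuple[float, float, float] | None = None,
    max_dose: float = 7.0,
    thickness: float = 20.0,
    penumbra_sigma: float = DEFAULT_PENUMBRA_SIGMA,
    attenuation_mu: float = DEFAULT_MU,
    total_duration: float = 19.0,
) -> tuple[PlanSpec, DoseVolume]:
    """C-shaped conformal plan: beam list plus the planned (deliverable) dose.

    ``n_beams`` equally spaced gantry angles receive non-negative
    aperture fluences (restricted to the beam's-eye-view silhouette of
    the C) fitted so their composite conforms to the ideal annular-
    sector target of :func:`cshape_target`.  Returns ``(plan, planned)``
    where ``planned`` is the plan's composite dose on ``grid`` — the
    dose a treatment planning system would report as the plan, including
    the unavoidable residual dose in the cold core and gap that
    non-negative external beams leave behind — scaled to ``max_dose``
    at its maximum.  The idealized C target itself is available from
    :func:`cshape_target`.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    iso = _default_isocenter(grid) if isocenter is None else np.asarray(isocenter, float)
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    if (iso[1] - outer_radius < lo[1] - 1e-9 or iso[1] + outer_radius > hi[1] + 1e-9
            or iso[2] - outer_radius < lo[2] - 1e-9 or iso[2] + outer_radius > hi[2] + 1e-9):
        raise ValueError("C-shape target exceeds the grid extent")

    angles = np.arange(n_beams) * 360.0 / n_beams
    if gap_angle >= 360.0:
        # fully open gap: empty target, zero-dose plan
        plan = PlanSpec(
            beams=(BeamSpec(
                field_size=(thickness, 2 * outer_radius), weight=0.0,
                penumbra_sigma=penumbra_sigma, attenuation_mu=attenuation_mu,
            ),),
            isocenter=tuple(iso), max_dose=max_dose,
            total_duration=total_duration,
        )
        return plan, DoseVolume(grid=grid, values=np.zeros(grid.shape))
    t_grid, fluences = _synthesize_apertures(
        outer_radius, inner_radius, gap_angle, angles, attenuation_mu,
        penumbra_sigma,
    )
    beams = []
    for ang, fluence in zip(angles, fluences):
        peak = fluence.max()
        if peak <= 0:
            continue
        beams.append(
            BeamSpec(
                field_size=(thickness, 2 * outer_radius),
                gantry_angle=ang,
                weight=peak,
                penumbra_sigma=penumbra_sigma,
                attenuation_mu=attenuation_mu,
                aperture=(t_grid, fluence / peak),
            )
        )
    plan = PlanSpec(
        beams=tuple(beams),
        isocenter=tuple(iso),
        max_dose=max_dose,
        total_duration=total_duration,
    )
    delivered_peak = composite_dose(plan, grid).values.max()
    scale = max_dose / delivered_peak
    plan = replace(
        plan, beams=tuple(replace(b, weight=b.weight * scale) for b in beams)
    )
    planned = composite_dose(plan, grid)
    return plan, planned


def rabbit_preset(
    grid: Grid3D,
    isocenter: tuple[float, float, float] | None = None,
    max_dose: float = 5.36,
    total_duration: float = 30.0,
) -> PlanSpec:
    """Four-beam anterior plan: 3 x 3 cm fields at gantry 30/40/320/340 deg.

    Equal beam weights, globally scaled so the composite maximum equals
    ``max_dose`` (Gy per fraction).
    """
    iso = _default_isocenter(grid) if isocenter is None else np.asarray(isocenter, float)
    beams = tuple(
        BeamSpec(field_size=(30.0, 30.0), gantry_angle=a, weight=1.0)
        for a in (30.0, 40.0, 320.0, 340.0)
    )
    plan = PlanSpec(
        beams=beams, isocenter=tuple(iso), max_dose=max_dose,
        total_duration=total_duration,
    )
    peak = composite_dose(plan, grid).values.max()
    if peak > 0:
        plan = replace(
            plan,
            beams=tuple(replace(b, weight=b.weight * max_dose / peak) for b in beams),
        )
    return plan


def delivery_timeline(
    plan: PlanSpec, prf_hz: float = DEFAULT_PRF_HZ
) -> list[tuple[int, float, float, int]]:
    """Per-beam delivery intervals: ``(beam index, start s, stop s, pulses)``.

    Durations are proportional to beam weights and partition
    ``[0, total_duration]``; pulse counts are the whole pulses fitting
    each interval at the accelerator pulse repetition frequency.
    """
    weights = np.array([b.weight for b in plan.beams], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("plan has zero total weight")
    durations = plan.total_duration * weights / weights.sum()
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    timeline = []
    for i in range(len(plan.beams)):
        # pulses fire on the global PRF clock; count those in [start, stop)
        first = int(np.ceil(edges[i] * prf_hz - 1e-9))
        last = int(np.ceil(edges[i + 1] * prf_hz - 1e-9))
        timeline.append((i, float(edges[i]), float(edges[i + 1]), last - first))
    return timeline
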