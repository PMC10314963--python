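"""Dosimetric image QA: PSF/LSF fits, beam widths, isodose, r.m.s.e., DAH.

All metrics operate on max-1-normalised images (inputs are normalised
first), so they are invariant to the arbitrary amplitude scale of the
acoustic chain.  Conventions follow radiotherapy QA practice: beam
width is the distance between 50%-of-maximum threshold crossings (the
field-size convention), resolution figures are the FWHM of least-
squares Gaussian fits, and the digital area histogram (DAH) is the 2D
analogue of a dose-volume histogram — the fraction of a region's area
receiving at least each relative dose level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage import measure

from .geometry import FWHM_SIGMA
from .recon import ReconVolume


@dataclass
class ProfileFit:
    """Least-squares Gaussian fit of a 1D profile."""

    coords: np.ndarray  # mm
    profile: np.ndarray
    amplitude: float
    center: float  # mm
    sigma: float  # mm
    baseline: float
    residual_norm: float

    @property
    def fwhm(self) -> float:
        """Full width at half maximum, mm (``2.3548 * sigma``)."""
        return FWHM_SIGMA * self.sigma

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.baseline + self.amplitude * np.exp(
            -0.5 * ((np.asarray(x) - self.center) / self.sigma) ** 2
        )


@dataclass
class DAHCurve:
    """Digital area histogram: area fraction at or above each dose level."""

    thresholds: np.ndarray  # fraction of maximum, 0..1
    area_fraction: np.ndarray
    mask_description: str = ""


@dataclass
class IsodoseSet:
    """Isodose contours of a 2D normalised image plane.

    ``contours[level]`` is a list of polylines in mm coordinates
    ``(axis0, axis1)`` of the image plane.
    """

    levels: tuple[float, ...]
    contours: dict


def _normalize(profile: np.ndarray) -> np.ndarray:
    peak = np.max(profile)
    if peak <= 0:
        raise ValueError("profile has no positive values")
    return profile / peak


def _gaussian(x, amplitude, center, sigma, baseline):
    return baseline + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fit_gaussian_profile(coords: np.ndarray, profile: np.ndarray) -> ProfileFit:
    """Gaussian + constant baseline least-squares fit of a sampled profile."""
    coords = np.asarray(coords, float)
    profile = np.asarray(profile, float)
    if coords.size < 5:
        raise ValueError("need at least 5 samples spanning the peak")
    p = _normalize(profile)
    i_max = int(np.argmax(p))
    above_half = np.flatnonzero(p >= 0.5)
    width0 = max(
        (coords[above_half[-1]] - coords[above_half[0]]) if above_half.size > 1
        else abs(coords[1] - coords[0]),
        abs(coords[1] - coords[0]),
    )
    guess = (1.0, coords[i_max], width0 / FWHM_SIGMA, float(p.min()))
    popt, _ = curve_fit(
        _gaussian, coords, p, p0=guess,
        bounds=([0.0, coords.min(), 1e-6, -1.0], [2.0, coords.max(), np.ptp(coords), 1.0]),
        maxfev=20000,
    )
    resid = p - _gaussian(coords, *popt)
    return ProfileFit(
        coords=coords, profile=p,
        amplitude=popt[0], center=popt[1], sigma=abs(popt[2]), baseline=popt[3],
        residual_norm=float(np.linalg.norm(resid)),
    )


def _extract_profile(
    recon: ReconVolume, axis: int, location: tuple[float, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """1D profile along ``axis`` through a point given in mm.

    ``location`` gives the mm coordinates on the two remaining axes, in
    ascending axis order.
    """
    grid = recon.grid
    other = [a for a in range(3) if a != axis]
    idx: list = [slice(None)] * 3
    for a, loc in zip(other, location):
        coords = grid.axis_coords(a)
        idx[a] = int(np.argmin(np.abs(coords - loc)))
    return grid.axis_coords(axis), recon.values[tuple(idx)]


def fit_psf(
    recon: ReconVolume,
    axis: int,
    location: tuple[float, float],
    window: tuple[float, float] | None = None,
) -> ProfileFit:
    """Point-spread-function fit: Gaussian fit of the intensity profile
    along ``axis`` through ``location`` (mm on the other two axes).
    """
    coords, profile = _extract_profile(recon, axis, location)
    if window is not None:
        sel = (coords >= window[0]) & (coords <= window[1])
        coords, profile = coords[sel], profile[sel]
    return fit_gaussian_profile(coords, profile)


def fit_lsf(
    recon: ReconVolume,
    axis: int,
    location: tuple[float, float],
    window: tuple[float, float],
) -> ProfileFit:
    """Line-spread-function fit from an edge response.

    Extracts the profile along ``axis`` (normally the axial/z
    direction) through ``location``, restricts it to ``window`` (mm, an
    interval bracketing one edge over which the response is monotone),
    differentiates it, and Gaussian-fits the derivative magnitude.  The
    FWHM of that fit is the edge (line-spread) resolution.
    """
    coords, profile = _extract_profile(recon, axis, location)
    sel = (coords >= window[0]) & (coords <= window[1])
    coords, profile = coords[sel], profile[sel]
    deriv = np.abs(np.gradient(profile, coords))
    return fit_gaussian_profile(coords, deriv)


def beam_width(
    recon: ReconVolume | np.ndarray,
    axis: int | None = None,
    location: tuple[float, float] | None = None,
    threshold: float = 0.5,
    coords: np.ndarray | None = None,
) -> float:
    """Width between the two ``threshold`` crossings of a max-1 profile.

    Either pass a :class:`ReconVolume` with ``axis`` and ``location``
    (mm), or a raw 1D profile with its ``coords``.  Crossings are
    located by linear interpolation between samples; the profile must
    have a single connected super-threshold run.
    """
    if isinstance(recon, ReconVolume):
        coords, profile = _extract_profile(recon, axis, location)
    else:
        profile = np.asarray(recon, float)
        if coords is None:
            raise ValueError("raw profiles need explicit coords")
    p = _normalize(profile)
    above = p >= threshold
    runs = np.flatnonzero(above)
    if runs.size == 0:
        raise ValueError("profile never reaches the threshold")
    if not np.all(np.diff(runs) == 1):
        raise ValueError("profile has multiple super-threshold runs")
    i0, i1 = runs[0], runs[-1]

    def _cross(i_out, i_in):
        if i_out < 0 or i_out >= p.size:
            return coords[i_in]
        f = (threshold - p[i_out]) / (p[i_in] - p[i_out])
        return coords[i_out] + f * (coords[i_in] - coords[i_out])

    left = _cross(i0 - 1, i0)
    right = _cross(i1 + 1, i1)
    return float(abs(right - left))


def superlevel_span(
    coords: np.ndarray, profile: np.ndarray, threshold: float = 0.5
) -> float:
    """Distance between the outermost ``threshold`` crossings of a profile.

    Unlike :func:`beam_width` this tolerates interior dips below the
    threshold (band-pass imaging renders wide slabs with bright edges
    and a dimmer interior): it spans from the first rising crossing to
    the last falling crossing of the max-1-normalised profile, with
    linear sub-sample interpolation.
    """
    coords = np.asarray(coords, float)
    p = _normalize(np.asarray(profile, float))
    idx = np.flatnonzero(p >= threshold)
    if idx.size == 0:
        raise ValueError("profile never reaches the threshold")
    i0, i1 = idx[0], idx[-1]

    def _cross(i_out, i_in):
        if i_out < 0 or i_out >= p.size:
            return coords[i_in]
        f = (threshold - p[i_out]) / (p[i_in] - p[i_out])
        return coords[i_out] + f * (coords[i_in] - coords[i_out])

    return float(abs(_cross(i1 + 1, i1) - _cross(i0 - 1, i0)))


def linearity(
    true_sizes: np.ndarray, measured: np.ndarray | list[list[float]]
) -> dict:
    """OLS of replicate-mean measured widths against true field sizes.

    ``measured`` is ``(n_sizes, n_replicates)`` (replicates may be a
    single column).  Returns slope, intercept, ``r_squared`` (coefficient
    of determination of the fit on replicate means), ``max_deviation``
    (max over all replicates of |measured - true|) and ``mean_sd`` (mean
    per-size replicate standard deviation).
    """
    true_sizes = np.asarray(true_sizes, float)
    measured = np.atleast_2d(np.asarray(measured, float))
    if true_sizes.size < 3:
        raise ValueError("need at least 3 sizes for a meaningful fit")
    if measured.shape[0] != true_sizes.size:
        raise ValueError("one row of replicates per true size required")
    means = measured.mean(axis=1)
    slope, intercept = np.polyfit(true_sizes, means, 1)
    fitted = slope * true_sizes + intercept
    ss_res = np.sum((means - fitted) ** 2)
    ss_tot = np.sum((means - means.mean()) ** 2)
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": float(r_squared),
        "max_deviation": float(np.max(np.abs(measured - true_sizes[:, None]))),
        "mean_sd": float(np.mean(measured.std(axis=1, ddof=1)))
        if measured.shape[1] > 1 else 0.0,
    }


def isodose(
    image: np.ndarray,
    levels: tuple[float, ...] = (0.6, 0.8),
    spacing: tuple[float, float] = (1.0, 1.0),
    origin: tuple[float, float] = (0.0, 0.0),
) -> IsodoseSet:
    """Marching-squares isodose contours of a max-1 2D image.

    Contour vertices are returned in mm (image axis order).  Superlevel
    sets nest by construction: higher levels lie within lower ones.
    """
    image = np.asarray(image, float)
    if not np.isclose(image.max(), 1.0, atol=1e-6):
        raise ValueError("image must be normalised to unit maximum")
    contours: dict = {}
    for level in levels:
        paths = measure.find_contours(image, level)
        contours[level] = [
            np.column_stack([
                origin[0] + p[:, 0] * spacing[0],
                origin[1] + p[:, 1] * spacing[1],
            ])
            for p in paths
        ]
    return IsodoseSet(levels=tuple(levels), contours=contours)


def comparison_mask(
    image_a: np.ndarray, image_b: np.ndarray, level: float = 0.2
) -> np.ndarray:
    """Default metric support: union superlevel set at ``level`` of max."""
    return (image_a >= level) | (image_b >= level)


def rmse_normalized(
    image_a: np.ndarray,
    image_b: np.ndarray,
    mask: np.ndarray | None = None,
    mask_level: float = 0.2,
) -> float:
    """Root mean square difference of two max-1 images over a mask.

    The default mask is the union 20%-of-max superlevel set, which
    excludes empty background that would otherwise deflate the error.
    """
    a = np.asarray(image_a, float)
    b = np.asarray(image_b, float)
    if a.shape != b.shape:
        raise ValueError("images must share a grid")
    for img in (a, b):
        if img.max() > 0 and not np.isclose(img.max(), 1.0, atol=1e-6):
            raise ValueError("images must be normalised to unit maximum")
    if mask is None:
        mask = comparison_mask(a, b, mask_level)
    if not mask.any():
        raise ValueError("empty comparison mask")
    return float(np.sqrt(np.mean((a[mask] - b[mask]) ** 2)))


def dah(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    thresholds: np.ndarray | None = None,
) -> DAHCurve:
    """Digital area histogram of a normalised 2D dose image.

    For each threshold ``q`` the curve gives the fraction of masked
    pixels with value >= q; it starts at 1 for q = 0 and is monotone
    non-increasing.
    """
    image = np.asarray(image, float)
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0 + 1e-9, 0.01)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = image[mask]
    frac = np.array([(vals >= q).mean() for q in thresholds])
    return DAHCurve(
        thresholds=np.asarray(thresholds, float), area_fraction=frac,
        mask_description=f"{int(mask.sum())} pixels",
    )


def repeatability(volumes: list[np.ndarray], mask_level: float = 0.2) -> float:
    """Percent variation across repeated normalised reconstructions.

    Each volume is normalised to unit maximum; the statistic is
    ``100 *`` the mean, over the union ``mask_level``-of-max superlevel
    set, of the voxelwise standard deviation across repeats.
    """
    if len(volumes) < 2:
        raise ValueError("need at least two repeats")
    arrs = []
    for v in volumes:
        a = np.asarray(v, float)
        peak = a.max()
        arrs.append(a / peak if peak > 0 else a)
    stack = np.stack(arrs)
    mask = np.any(stack >= mask_level, axis=0)
    if not mask.any():
        raise ValueError("empty repeatability mask")
    sd = stack.std(axis=0, ddof=1)
    return float(100.0 * sd[mask].mean())
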