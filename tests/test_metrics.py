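"""QA metrics: fits, widths, isodose, r.m.s.e., DAH, repeatability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

import irai
from irai import metrics
from irai.geometry import FWHM_SIGMA


def volume_from_z_profile(z0, z1, dz, profile_fn):
    z = np.arange(z0, z1 + dz / 2, dz)
    g = irai.Grid3D.from_extent((-1, 1), (-1, 1), (z0, z1), (1.0, 1.0, dz))
    vals = np.broadcast_to(profile_fn(z), (3, 3, z.size)).copy()
    return irai.ReconVolume(grid=g, values=vals)


class TestGaussianFits:
    def test_exact_gaussian_fwhm(self):
        vol = volume_from_z_profile(
            80, 120, 0.5, lambda z: np.exp(-0.5 * ((z - 100) / 2.0) ** 2)
        )
        fit = metrics.fit_psf(vol, axis=2, location=(0.0, 0.0))
        assert fit.fwhm == pytest.approx(FWHM_SIGMA * 2.0, abs=1e-6)
        assert fit.fwhm == pytest.approx(4.7096, abs=1e-3)

    @pytest.mark.parametrize("k", [0.1, 3.0, 1e4])
    def test_fwhm_scale_invariant(self, k):
        vol = volume_from_z_profile(
            80, 120, 0.5, lambda z: k * np.exp(-0.5 * ((z - 100) / 3.0) ** 2)
        )
        fit = metrics.fit_psf(vol, axis=2, location=(0.0, 0.0))
        assert fit.fwhm == pytest.approx(FWHM_SIGMA * 3.0, rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            metrics.fit_gaussian_profile(np.arange(3), np.array([0, 1, 0]))

    def test_lsf_from_ideal_erf_edge(self):
        """Edge blurred by sigma = 1.7 mm -> LSF FWHM = 2.3548 * 1.7."""
        sigma = 1.7
        vol = volume_from_z_profile(
            80, 120, 0.25,
            lambda z: 0.5 * (1 + erf((z - 100) / (np.sqrt(2) * sigma))),
        )
        fit = metrics.fit_lsf(vol, axis=2, location=(0.0, 0.0), window=(90, 110))
        # second-order finite differencing costs ~0.4% on this sampling
        assert fit.fwhm == pytest.approx(FWHM_SIGMA * sigma, rel=5e-3)
        assert fit.fwhm == pytest.approx(4.003, abs=0.02)

    @pytest.mark.parametrize("kernel_sigma", [1.0, 2.5])
    def test_lsf_recovers_blur_kernel(self, kernel_sigma):
        """A step blurred by a known Gaussian: recovered FWHM within 5%."""
        dz = 0.25
        z = np.arange(80, 120 + dz / 2, dz)
        step = (z >= 100).astype(float)
        from scipy.ndimage import gaussian_filter1d

        blurred = gaussian_filter1d(step, kernel_sigma / dz)
        vol = volume_from_z_profile(80, 120, dz, lambda zz: blurred)
        fit = metrics.fit_lsf(vol, axis=2, location=(0.0, 0.0), window=(90, 110))
        assert fit.fwhm == pytest.approx(FWHM_SIGMA * kernel_sigma, rel=0.05)


class TestBeamWidth:
    def test_binary_slab(self):
        z = np.arange(0, 100.0)
        prof = ((z >= 35) & (z < 65)).astype(float)
        assert metrics.beam_width(prof, coords=z) == pytest.approx(30.0, abs=1.0)

    @pytest.mark.parametrize("sigma", [1.0, 2.0, 4.0])
    def test_erf_slab_exact_at_half_threshold(self, sigma):
        """The 50% crossings of an erf-edged slab sit exactly at the
        nominal edges, for any penumbra width."""
        z = np.arange(0, 200.0, 0.25)
        s = np.sqrt(2) * sigma
        prof = 0.5 * (erf((z - 70) / s) - erf((z - 130) / s))
        assert metrics.beam_width(prof, coords=z) == pytest.approx(60.0, abs=1e-2)

    def test_multiple_runs_rejected(self):
        z = np.arange(0, 50.0)
        prof = ((z < 10) | (z > 40)).astype(float)
        prof[0] = 0.0
        with pytest.raises(ValueError):
            metrics.beam_width(prof, coords=z)

    def test_superlevel_span_bridges_interior_dip(self):
        z = np.arange(0, 100.0, 0.5)
        prof = np.exp(-0.5 * ((z - 30) / 3) ** 2) + np.exp(-0.5 * ((z - 70) / 3) ** 2)
        span = metrics.superlevel_span(z, prof)
        # outer half-max crossings of the two humps: 30 - h/2 .. 70 + h/2
        assert span == pytest.approx(40.0 + FWHM_SIGMA * 3.0, abs=0.3)


class TestLinearity:
    def test_perfect_measurements(self):
        sizes = np.array([10.0, 20.0, 30.0])
        out = metrics.linearity(sizes, sizes[:, None])
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["max_deviation"] == 0.0

    def test_slope_two_still_r2_one(self):
        sizes = np.array([10.0, 20.0, 30.0])
        out = metrics.linearity(sizes, (2 * sizes)[:, None])
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_hand_computed_three_points(self):
        """OLS on (1,2), (2,2.5), (3,4): slope 1, intercept 0.8333,
        r^2 = 1 - 0.1667/2.1667 (computed by hand)."""
        sizes = np.array([1.0, 2.0, 3.0])
        measured = np.array([[2.0], [2.5], [4.0]])
        out = metrics.linearity(sizes, measured)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.8333, abs=1e-4)
        assert out["r_squared"] == pytest.approx(1 - (1 / 6) / (13 / 6), abs=1e-9)
        assert out["max_deviation"] == pytest.approx(1.0)

    def test_replicate_sd(self):
        sizes = np.array([10.0, 20.0, 30.0])
        measured = np.array([[9, 11], [19, 21], [29, 31]], dtype=float)
        out = metrics.linearity(sizes, measured)
        assert out["mean_sd"] == pytest.approx(np.std([9, 11], ddof=1))


class TestIsodose:
    def test_disk_half_level_contour(self):
        """Hard-edged disk: the 0.5 contour is a circle of the disk radius."""
        n, r = 101, 30.0
        yy, xx = np.mgrid[:n, :n] - n // 2
        img = (np.hypot(xx, yy) <= r).astype(float)
        iso = metrics.isodose(img, levels=(0.5,), origin=(-(n // 2), -(n // 2)))
        (contour,) = iso.contours[0.5]
        radii = np.hypot(contour[:, 0], contour[:, 1])
        assert np.abs(radii - r).max() < 1.0  # Hausdorff < 1 px

    def test_nested_levels_on_c_shape(self):
        grid = irai.Grid3D.from_extent((-30, 30), (-30, 30), (70, 130), 1.0)
        target = irai.cshape_target(grid, (0, 0, 100))
        img = target.values[30] / target.values[30].max()
        iso = metrics.isodose(img, levels=(0.6, 0.8))
        assert len(iso.contours[0.6]) >= 1 and len(iso.contours[0.8]) >= 1
        # nesting: every point of the 0.8 contour lies inside the 0.6 region
        for poly in iso.contours[0.8]:
            vals = img[
                np.clip(np.round(poly[:, 0]).astype(int), 0, img.shape[0] - 1),
                np.clip(np.round(poly[:, 1]).astype(int), 0, img.shape[1] - 1),
            ]
            assert np.all(vals >= 0.6 - 0.05)

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError):
            metrics.isodose(np.full((8, 8), 0.4))


class TestRmse:
    def test_identity(self):
        img = np.random.default_rng(0).random((16, 16))
        img /= img.max()
        assert metrics.rmse_normalized(img, img) == 0.0

    def test_constant_offset(self):
        a = np.ones((8, 8))
        b = np.full((8, 8), 0.9)
        b[0, 0] = 1.0  # keep max-1 normalisation honest
        assert metrics.rmse_normalized(a, b) == pytest.approx(0.1, abs=0.01)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((12, 12))
        b = rng.random((12, 12))
        a /= a.max()
        b /= b.max()
        r_ab = metrics.rmse_normalized(a, b)
        r_ba = metrics.rmse_normalized(b, a)
        assert r_ab >= 0.0
        assert r_ab == pytest.approx(r_ba)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            metrics.rmse_normalized(np.ones((4, 4)), np.ones((5, 5)))


class TestDAH:
    def test_uniform_image(self):
        curve = metrics.dah(np.full((10, 10), 0.7))
        assert np.all(curve.area_fraction[curve.thresholds <= 0.7] == 1.0)
        assert np.all(curve.area_fraction[curve.thresholds > 0.7] == 0.0)

    def test_linear_ramp(self):
        """Uniformly distributed values: DAH(q) = 1 - q."""
        n = 501
        img = np.tile(np.linspace(0, 1, n), (3, 1))
        curve = metrics.dah(img)
        np.testing.assert_allclose(
            curve.area_fraction, 1.0 - curve.thresholds, atol=1.5 / n
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_with_endpoints(self, seed):
        img = np.random.default_rng(seed).random((20, 20))
        curve = metrics.dah(img / img.max())
        assert curve.area_fraction[0] == 1.0
        assert np.all(np.diff(curve.area_fraction) <= 1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            metrics.dah(np.ones((4, 4)), mask=np.zeros((4, 4), dtype=bool))


class TestRepeatability:
    def test_identical_volumes(self):
        v = np.random.default_rng(2).random((8, 8, 8))
        assert metrics.repeatability([v, v.copy(), v.copy()]) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_known_sd(self):
        """Voxelwise s.d. of 0.01 injected on the mask reads out as 1.0%."""
        base = np.full((6, 6, 6), 0.5)
        base[0, 0, 0] = 1.0  # normalisation anchor
        delta = 0.01 / np.sqrt(2)  # sd of {x+d, x-d} with ddof=1 is d*sqrt(2)
        v1, v2 = base.copy(), base.copy()
        v1[1:, :, :] += delta
        v2[1:, :, :] -= delta
        out = metrics.repeatability([v1, v2])
        mask_total = 6 * 6 * 6
        varying = mask_total - 36
        assert out == pytest.approx(1.0 * varying / mask_total, rel=0.01)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            metrics.repeatability([np.ones((4, 4, 4))])
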