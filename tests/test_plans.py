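"""Dose synthesis: rectangular beams, C-shape plan, presets, timelines."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.special import erf

import irai
from irai.plans import beam_axes, composite_dose, delivery_timeline


@pytest.fixture(scope="module")
def grid():
    return irai.Grid3D.from_extent((-30, 30), (-30, 30), (70, 130), 2.0)


class TestRectangularBeam:
    def test_sharp_field_width_between_half_levels(self):
        """5 x 5 mm field with vanishing penumbra: a binary 5 mm slab."""
        g = irai.Grid3D.from_extent((-10, 10), (-10, 10), (90, 110), 0.5)
        beam = irai.BeamSpec(field_size=(5.0, 5.0), penumbra_sigma=0.0,
                             attenuation_mu=0.0)
        dose = irai.rectangular_beam_dose(beam, g, isocenter=(0, 0, 100))
        prof = dose.values[:, 20, 20]
        xs = g.axis_coords(0)
        width = irai.metrics.beam_width(prof, coords=xs)
        assert width == pytest.approx(5.0, abs=0.5)  # half-voxel quantisation
        assert set(np.unique(dose.values)) <= {0.0, 1.0}

    def test_zero_weight_zero_volume(self, grid):
        beam = irai.BeamSpec(field_size=(10, 10), weight=0.0)
        dose = irai.rectangular_beam_dose(beam, grid)
        assert not dose.values.any()

    def test_missed_grid_warns(self):
        g = irai.Grid3D.from_extent((-5, 5), (-5, 5), (95, 105), 1.0)
        beam = irai.BeamSpec(field_size=(4, 4), penumbra_sigma=0.0, offset_t=500.0)
        with pytest.warns(UserWarning):
            dose = irai.rectangular_beam_dose(beam, g, isocenter=(0, 0, 100))
        assert not dose.values.any()

    def test_erf_edge_closed_form(self):
        """Profile at the nominal edge is exactly half the open-field value."""
        g = irai.Grid3D.from_extent((-25, 25), (-20, 20), (80, 120), 1.0)
        sigma, mu = 2.0, 0.005
        beam = irai.BeamSpec(field_size=(30.0, 10.0), penumbra_sigma=sigma,
                             attenuation_mu=mu)
        dose = irai.rectangular_beam_dose(beam, g, isocenter=(0, 0, 100),
                                          normalize=False)
        ix_edge = np.argmin(np.abs(g.axis_coords(0) - 15.0))  # x = wx/2
        iy = np.argmin(np.abs(g.axis_coords(1)))
        iz = np.argmin(np.abs(g.axis_coords(2) - 100.0))
        s = np.sqrt(2) * sigma
        expected = (
            0.5 * (erf(30.0 / s) - erf(0.0))       # x edge pair at x = wx/2
            * 0.5 * (erf(5.0 / s) - erf(-5.0 / s))  # z pair (half-width 5) at z0
        )
        assert dose.values[ix_edge, iy, iz] == pytest.approx(expected, rel=1e-9)
        # depth attenuation: downstream (-y) falls off as exp(-mu s)
        iy2 = np.argmin(np.abs(g.axis_coords(1) + 10.0))
        ratio = dose.values[ix_edge, iy2, iz] / dose.values[ix_edge, iy, iz]
        assert ratio == pytest.approx(np.exp(-mu * 10.0), rel=1e-9)

    @pytest.mark.parametrize("k", [0.5, 2.0, 7.0])
    def test_dose_linear_in_weight(self, grid, k):
        b1 = irai.BeamSpec(field_size=(10, 10), weight=1.0)
        bk = irai.BeamSpec(field_size=(10, 10), weight=k)
        d1 = irai.rectangular_beam_dose(b1, grid)
        dk = irai.rectangular_beam_dose(bk, grid)
        np.testing.assert_allclose(dk.values, k * d1.values, rtol=1e-12)

    def test_full_turn_rotation_identity(self, grid):
        base = irai.BeamSpec(field_size=(10, 20), gantry_angle=0.0)
        turned = irai.BeamSpec(field_size=(10, 20), gantry_angle=360.0)
        d0 = irai.rectangular_beam_dose(base, grid)
        d1 = irai.rectangular_beam_dose(turned, grid)
        assert np.abs(d1.values - d0.values).max() < 1e-6 * d0.values.max()

    def test_quarter_turn_swaps_axes(self):
        """At gantry 90 the beam travels along -z; the transverse field
        axis lands on -y (right-handed frame)."""
        d, t_hat = beam_axes(90.0)
        np.testing.assert_allclose(d, [0, 0, -1], atol=1e-12)
        np.testing.assert_allclose(t_hat, [0, -1, 0], atol=1e-12)


@pytest.fixture(scope="module")
def cplan(grid):
    return irai.cshape_plan(grid, isocenter=(0, 0, 100))


class TestCShapePlan:
    def test_default_plan_shape(self, cplan, grid):
        plan, planned = cplan
        assert len(plan.beams) == 23
        assert planned.values.max() == pytest.approx(7.0)

    def test_planned_equals_delivered_composite(self, cplan, grid):
        plan, planned = cplan
        delivered = composite_dose(plan, grid)
        np.testing.assert_allclose(delivered.values, planned.values, rtol=1e-9)

    def test_cold_core_spared(self, cplan, grid):
        """The composite keeps the central core well below the annulus dose."""
        plan, planned = cplan
        gx, gy, gz = grid.meshgrid()
        rho = np.hypot(gy, gz - 100.0)
        core = (rho < 8.0) & (np.abs(gx) < 8.0)
        annulus = (rho > 14) & (rho < 23) & (np.abs(gx) < 8.0) & (gy < 0)
        assert planned.values[core].mean() < 0.5 * planned.values[annulus].mean()

    def test_single_beam_is_worse_than_23(self, grid):
        """One silhouette beam misses the C target much more than 23 beams."""
        target = irai.cshape_target(grid, (0, 0, 100)).values
        target = target / target.max()
        ix = target.shape[0] // 2
        rmses = {}
        for n in (1, 23):
            _, planned = irai.cshape_plan(grid, n_beams=n, isocenter=(0, 0, 100))
            img = planned.values[ix] / planned.values[ix].max()
            rmses[n] = irai.metrics.rmse_normalized(img, target[ix])
        assert rmses[1] > rmses[23]

    def test_open_gap_is_empty(self, grid):
        plan, planned = irai.cshape_plan(grid, gap_angle=360.0,
                                         isocenter=(0, 0, 100))
        assert not planned.values.any()

    def test_target_outside_grid_rejected(self):
        small = irai.Grid3D.from_extent((-5, 5), (-5, 5), (95, 105), 2.0)
        with pytest.raises(ValueError):
            irai.cshape_plan(small)


@pytest.fixture(scope="module")
def rplan(grid):
    return irai.rabbit_preset(grid, isocenter=(0, 0, 100))


class TestRabbitPreset:
    def test_four_beams_and_max_dose(self, rplan, grid):
        assert len(rplan.beams) == 4
        assert sorted(b.gantry_angle for b in rplan.beams) == [30, 40, 320, 340]
        assert all(b.field_size == (30.0, 30.0) for b in rplan.beams)
        assert composite_dose(rplan, grid).values.max() == pytest.approx(5.36)

    def test_single_beam_max_equals_weight(self, rplan, grid):
        beam = rplan.beams[0]
        alone = irai.rectangular_beam_dose(beam, grid, isocenter=rplan.isocenter)
        assert alone.values.max() == pytest.approx(beam.weight)

    def test_hot_region_inside_beam_intersection(self, rplan, grid):
        """The 80% isodose volume concentrates where all four beams overlap."""
        comp = composite_dose(rplan, grid)
        hot = comp.values >= 0.8 * comp.values.max()
        inter = np.ones(grid.shape, dtype=bool)
        for b in rplan.beams:
            single = irai.rectangular_beam_dose(
                b, grid, isocenter=rplan.isocenter, normalize=True
            )
            inter &= single.values >= 0.45 * single.values.max()
        # allow the penumbra: dilate the geometric intersection by ~sigma
        inter = ndimage.binary_dilation(inter, iterations=2)
        assert hot.any() and np.all(inter[hot])


class TestDeliveryTimeline:
    def test_equal_weights_partition(self):
        plan, _ = irai.cshape_plan(
            irai.Grid3D.from_extent((-30, 30), (-30, 30), (70, 130), 2.0),
            isocenter=(0, 0, 100),
        )
        tl = delivery_timeline(plan)
        assert tl[0][1] == 0.0
        assert tl[-1][2] == pytest.approx(plan.total_duration)
        for prev, nxt in zip(tl[:-1], tl[1:]):
            assert prev[2] == pytest.approx(nxt[1])
        total_pulses = sum(n for *_, n in tl)
        assert total_pulses == int(np.ceil(plan.total_duration * 360.0 - 1e-9))

    def test_single_beam_interval(self):
        plan = irai.PlanSpec(
            beams=(irai.BeamSpec(field_size=(10, 10)),),
            isocenter=(0, 0, 100), max_dose=1.0, total_duration=5.0,
        )
        (idx, start, stop, n), = delivery_timeline(plan)
        assert (idx, start, stop) == (0, 0.0, 5.0)
        assert n == 1800  # 5 s at 360 Hz

    def test_durations_proportional_to_weights(self):
        beams = tuple(
            irai.BeamSpec(field_size=(10, 10), weight=w) for w in (2.0, 1.0, 1.0)
        )
        plan = irai.PlanSpec(beams=beams, isocenter=(0, 0, 100),
                             max_dose=1.0, total_duration=8.0)
        tl = delivery_timeline(plan)
        durations = [stop - start for _, start, stop, _ in tl]
        assert durations == pytest.approx([4.0, 2.0, 2.0])

    def test_equal_23_beam_durations(self):
        """23 equal beams over 19 s -> ~0.826 s each."""
        beams = tuple(
            irai.BeamSpec(field_size=(10, 10), weight=1.0) for _ in range(23)
        )
        plan = irai.PlanSpec(beams=beams, isocenter=(0, 0, 100),
                             max_dose=7.0, total_duration=19.0)
        durations = [stop - start for _, start, stop, _ in delivery_timeline(plan)]
        assert durations == pytest.approx([19.0 / 23] * 23)
        assert durations[0] == pytest.approx(0.826, abs=5e-4)
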