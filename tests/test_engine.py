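"""Dose engine: tracing, depth dose, beams, plans, wedges."""

import math

import numpy as np
import pytest

from xpanderdose import (
    BeamSpec,
    PlanSpec,
    WedgeSpec,
    arc_to_beams,
    build_ic_phantom,
    compute_beam_dose,
    compute_plan_dose,
    pdd,
    point_dose,
    radiological_depth,
    wedge_factor,
)
from xpanderdose.engine import DEFAULT_BEAM_DATA, effective_slope
from xpanderdose.volume import centered_grid

ENERGIES = (6, 10, 15)


def water_tank(spacing=(2, 2, 2), **kwargs):
    build = build_ic_phantom(orientation="perpendicular", spacing=spacing, **kwargs)
    build.volume.values[:] = 1.0
    return build.volume


def anterior_beam(energy=6, **kwargs):
    defaults = dict(energy_mv=energy, gantry_deg=0.0, ssd_mm=850.0, sad_mm=None, isocenter=(0, 150, 0))
    defaults.update(kwargs)
    return BeamSpec(**defaults)


class TestRadiologicalDepth:
    def test_uniform_water(self):
        vol = water_tank(spacing=(1, 1, 1), lateral_mm=40)
        assert radiological_depth(vol, (0, -500, 0), (0, 100, 0)) == pytest.approx(10.0, abs=1e-6)

    def test_water_plus_port_slab(self):
        build = build_ic_phantom(orientation="perpendicular", spacing=(1, 1, 1), lateral_mm=40)
        got = radiological_depth(build.volume, (0, -500, 0), (0, 150, 0))
        assert got == pytest.approx(14.5 + 0.5 * 7.5, abs=1e-6)

    def test_oblique_ray_matches_dense_sampling(self):
        vol = centered_grid((60, 60, 60), (2, 2, 2), fill=1.0)
        vol.values[:, vol.axis_coords(1) > 10, :] = 0.3  # slab boundary
        src = np.array([-40.0, -40.0, -10.0])
        tgt = np.array([25.0, 25.0, 5.0])
        got = radiological_depth(vol, src, tgt)
        # dense nearest-voxel sampling at 1 um steps
        n = int(np.linalg.norm(tgt - src) / 0.001)
        ts = np.linspace(0.0, 1.0, n)
        pts = src[None, :] + ts[:, None] * (tgt - src)[None, :]
        idx = np.floor(vol.world_to_index(pts) + 0.5).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(vol.dims)), axis=1)
        rho = np.zeros(n)
        rho[inside] = vol.values[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        oracle = rho.sum() * np.linalg.norm(tgt - src) / n / 10.0
        assert got == pytest.approx(oracle, rel=0.001)

    def test_hu_volume_rejected(self):
        vol = water_tank()
        vol.unit = "HU"
        with pytest.raises(ValueError):
            radiological_depth(vol, (0, -500, 0), (0, 100, 0))


class TestPdd:
    @pytest.mark.parametrize("energy", ENERGIES)
    def test_unity_at_dmax(self, energy):
        dmax = DEFAULT_BEAM_DATA[energy].dmax_mm
        assert pdd(energy, dmax) == pytest.approx(1.0)

    @pytest.mark.parametrize("energy", ENERGIES)
    def test_buildup_below_unity_at_surface(self, energy):
        assert pdd(energy, 0.0) < 1.0

    def test_higher_energy_penetrates_deeper(self):
        assert pdd(6, 100.0) < pdd(15, 100.0)

    def test_unknown_energy_rejected(self):
        with pytest.raises(ValueError):
            pdd(4, 100.0)

    def test_mu_decreases_with_energy(self):
        mus = [DEFAULT_BEAM_DATA[e].mu_rho for e in ENERGIES]
        assert mus[0] > mus[1] > mus[2] > 0


class TestBeamDose:
    def test_water_anchor_matches_closed_form(self):
        vol = water_tank()
        ix, iz = vol.dims[0] // 2, vol.dims[2] // 2
        x0, z0 = vol.axis_coords(0)[ix], vol.axis_coords(2)[iz]
        ys = vol.axis_coords(1)
        sel = (ys >= 10) & (ys <= 200)
        for energy in ENERGIES:
            dose = compute_beam_dose(vol, anterior_beam(energy), primary_only=True)
            dist = np.sqrt(x0**2 + z0**2 + (850.0 + ys) ** 2)
            closed = (1000.0 / dist) ** 2 * pdd(energy, ys)
            rel = dose.values[ix, sel, iz] / closed[sel]
            assert np.all(np.abs(rel - 1.0) < 0.01)

    def test_port_attenuation_matches_exponential(self):
        # 1 mm spacing along the beam keeps the voxelized chord exact
        build = build_ic_phantom(orientation="perpendicular", spacing=(2, 1, 2), lateral_mm=120)
        water = build.volume.copy_with(values=np.ones_like(build.volume.values))
        beam = anterior_beam(6)
        with_port = compute_beam_dose(build.volume, beam, primary_only=True)
        without = compute_beam_dose(water, beam, primary_only=True)
        ix, iz = build.volume.dims[0] // 2, build.volume.dims[2] // 2
        ys = build.volume.axis_coords(1)
        sel = (ys >= 80) & (ys <= 200)
        ratio = with_port.values[ix, sel, iz] / without.values[ix, sel, iz]
        expected = math.exp(-0.0493 * (7.5 - 1.0) * 0.5)
        assert np.all(np.abs(ratio / expected - 1.0) < 0.03)

    def test_port_strictly_reduces_downstream_dose(self):
        build = build_ic_phantom(orientation="perpendicular", spacing=(2, 1, 2), lateral_mm=120)
        water = build.volume.copy_with(values=np.ones_like(build.volume.values))
        beam = anterior_beam(6)
        with_port = compute_beam_dose(build.volume, beam)
        without = compute_beam_dose(water, beam)
        ix, iz = build.volume.dims[0] // 2, build.volume.dims[2] // 2
        ys = build.volume.axis_coords(1)
        beyond = ys >= build.port.center[1] + build.port.thickness / 2 + 10.0
        assert np.all(with_port.values[ix, beyond, iz] < without.values[ix, beyond, iz])

    def test_mirrored_phantom_and_beam_give_mirrored_dose(self):
        build = build_ic_phantom(orientation="parallel", spacing=(2, 2, 2))
        beam = BeamSpec(energy_mv=6, gantry_deg=30.0, sad_mm=1000.0, isocenter=(0, 150, 0))
        mirrored_beam = BeamSpec(energy_mv=6, gantry_deg=-30.0, sad_mm=1000.0, isocenter=(0, 150, 0))
        dose = compute_beam_dose(build.volume, beam)
        flipped = build.volume.copy_with(values=build.volume.values[::-1, :, :].copy())
        dose_m = compute_beam_dose(flipped, mirrored_beam)
        diff = np.abs(dose_m.values[::-1, :, :] - dose.values).max()
        assert diff < 1e-6 * dose.values.max()

    def test_perpendicular_shadow_wider_parallel_deeper(self):
        from xpanderdose.evaluation import fwhm

        beam = anterior_beam(6)
        shadows = {}
        for orient in ("perpendicular", "parallel"):
            build = build_ic_phantom(orientation=orient, spacing=(1, 1, 2), lateral_mm=100)
            water = build.volume.copy_with(values=np.ones_like(build.volume.values))
            ratio_num = compute_beam_dose(build.volume, beam)
            ratio_den = compute_beam_dose(water, beam)
            ys = build.volume.axis_coords(1)
            k = int(np.argmin(np.abs(ys - 110.0)))  # ~5 cm past the port
            iz = build.volume.dims[2] // 2
            profile = ratio_num.values[:, k, iz] / ratio_den.values[:, k, iz]
            shadows[orient] = (fwhm(profile, 1.0), 1.0 - profile.min())
        assert shadows["perpendicular"][0] > shadows["parallel"][0]
        assert shadows["parallel"][1] > shadows["perpendicular"][1]

    def test_beam_missing_volume_gives_zero_dose(self):
        # central axis pointing away from the tank: no surface entry
        vol = water_tank()
        beam = BeamSpec(energy_mv=6, gantry_deg=180.0, ssd_mm=850.0, sad_mm=None, isocenter=(0, -2000, 0))
        dose = compute_beam_dose(vol, beam)
        assert dose.values.max() == 0.0


class TestPlanDose:
    def test_single_beam_plan_equals_normalized_beam(self):
        vol = water_tank()
        beam = anterior_beam(6)
        plan = PlanSpec(beams=(beam,), prescription_gy=1.0, norm_point=(0, 150, 0))
        plan_dose = compute_plan_dose(vol, plan)
        beam_dose = compute_beam_dose(vol, beam)
        scale = 1.0 / point_dose(beam_dose, (0, 150, 0))
        np.testing.assert_allclose(plan_dose.values, beam_dose.values * scale, rtol=1e-12)

    def test_opposed_pair_symmetric_and_normalized(self):
        vol = centered_grid((160, 160, 120), (2, 2, 2), fill=1.0)
        beams = tuple(
            BeamSpec(energy_mv=6, gantry_deg=g, sad_mm=1000.0, isocenter=(0, 0, 0)) for g in (90, 270)
        )
        plan = PlanSpec(beams=beams, prescription_gy=1.0)
        dose = compute_plan_dose(vol, plan)
        assert point_dose(dose, (0, 0, 0)) == pytest.approx(1.0, abs=1e-9)
        mirrored = dose.values[::-1, :, :]
        sel = dose.values > 0.1
        assert np.max(np.abs(mirrored[sel] - dose.values[sel]) / dose.values[sel]) < 0.005

    def test_zero_weight_plan_rejected(self):
        vol = water_tank()
        plan = PlanSpec(beams=(anterior_beam(weight=0.0),), prescription_gy=1.0)
        with pytest.raises(ValueError):
            compute_plan_dose(vol, plan)


class TestArc:
    def test_half_arc_at_10_degrees_gives_19_beams(self):
        beams = arc_to_beams(90, 270, 10, BeamSpec(energy_mv=6, sad_mm=1000))
        assert len(beams) == 19
        assert beams[0].gantry_deg == 90 and beams[-1].gantry_deg == 270

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError):
            arc_to_beams(90, 90, 10, BeamSpec(energy_mv=6, sad_mm=1000))
        with pytest.raises(ValueError):
            arc_to_beams(90, 270, 0, BeamSpec(energy_mv=6, sad_mm=1000))

    def test_equal_weights(self):
        beams = arc_to_beams(0, 90, 30, BeamSpec(energy_mv=6, sad_mm=1000, weight=2.0))
        assert all(b.weight == 2.0 for b in beams)


class TestWedge:
    def test_no_wedge_unity(self):
        assert wedge_factor(None, 37.0) == 1.0

    def test_center_unity_any_angle(self):
        for angle in (10, 20, 45):
            assert wedge_factor(WedgeSpec(angle_deg=angle), 0.0) == pytest.approx(1.0)

    def test_transmission_in_unit_interval(self):
        w = WedgeSpec(angle_deg=45, orientation=+1)
        u = np.linspace(-60, 60, 101)
        f = wedge_factor(w, u)
        assert np.all(f > 0) and np.all(f <= 1.0)

    def test_nominal_angle_matches_isodose_tilt_at_10cm(self):
        vol = water_tank()
        beam = BeamSpec(
            energy_mv=6,
            gantry_deg=0.0,
            sad_mm=1000.0,
            isocenter=(0, 100, 0),
            wedge=WedgeSpec(angle_deg=20.0, orientation=+1),
        )
        dose = compute_beam_dose(vol, beam, primary_only=True)
        level = point_dose(dose, (0, 100, 1))
        yy = np.arange(40.0, 140.0, 0.25)
        xs, depths = [], []
        for x in np.arange(2.0, 16.1, 2.0):  # attenuated (toe) side, near axis
            profile = np.array([point_dose(dose, (x, y, 1)) for y in yy])
            below = np.nonzero(profile < level)[0]
            i = below[0]
            crossing = yy[i - 1] + (profile[i - 1] - level) / (profile[i - 1] - profile[i]) * 0.25
            xs.append(x)
            depths.append(crossing)
        slope = np.polyfit(xs, depths, 1)[0]
        tilt = math.degrees(math.atan(-slope))
        assert tilt == pytest.approx(20.0, abs=1.0)

    def test_slope_uses_depth_dose_gradient(self):
        # steeper depth-dose (lower energy) needs a steeper wedge gradient
        f6 = wedge_factor(WedgeSpec(angle_deg=20), 30.0, energy_mv=6)
        f15 = wedge_factor(WedgeSpec(angle_deg=20), 30.0, energy_mv=15)
        assert f6 < f15
        assert effective_slope(6) > effective_slope(15)


class TestPointDose:
    def test_voxel_center_value(self):
        vol = water_tank()
        dose = vol.copy_with(values=np.arange(np.prod(vol.dims)).reshape(vol.dims).astype(float), unit="Gy")
        idx = (3, 4, 5)
        pt = vol.origin + np.array(idx) * vol.spacing
        assert point_dose(dose, pt) == dose.values[idx]

    def test_midpoint_is_arithmetic_mean(self):
        vol = water_tank()
        dose = vol.copy_with(values=np.random.default_rng(0).random(vol.dims), unit="Gy")
        idx = np.array([3, 4, 5])
        pt = vol.origin + idx * vol.spacing + np.array([vol.spacing[0] / 2, 0, 0])
        expected = 0.5 * (dose.values[3, 4, 5] + dose.values[4, 4, 5])
        assert point_dose(dose, pt) == pytest.approx(expected)

    def test_interpolation_within_neighbor_range(self, rng):
        vol = water_tank()
        dose = vol.copy_with(values=rng.random(vol.dims), unit="Gy")
        for _ in range(50):
            idx = rng.uniform(0, np.array(vol.dims) - 1.001)
            pt = vol.origin + idx * vol.spacing
            lo = np.floor(idx).astype(int)
            block = dose.values[lo[0] : lo[0] + 2, lo[1] : lo[1] + 2, lo[2] : lo[2] + 2]
            val = point_dose(dose, pt)
            assert block.min() - 1e-12 <= val <= block.max() + 1e-12

    def test_outside_grid_rejected(self):
        vol = water_tank()
        dose = vol.copy_with(unit="Gy")
        with pytest.raises(ValueError):
            point_dose(dose, (0, -5, 0))


class TestEnergyConservation:
    def test_upstream_densification_reduces_transmitted_dose(self):
        vol = water_tank(spacing=(2, 2, 2))
        beam = anterior_beam(6)
        base = compute_beam_dose(vol, beam, primary_only=True)
        denser = vol.copy_with()
        sel = (vol.axis_coords(1) > 40) & (vol.axis_coords(1) < 60)
        denser.values[:, sel, :] = 2.0
        attenuated = compute_beam_dose(denser, beam, primary_only=True)
        ys = vol.axis_coords(1)
        downstream = ys > 70
        assert attenuated.values[:, downstream, :].sum() < base.values[:, downstream, :].sum()
        assert np.all(base.values >= 0) and np.all(attenuated.values >= 0)
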