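"""Phantom factory: tanks, slabs, artifacts, conversion tables, overrides."""

import numpy as np
import pytest

from xpanderdose import (
    EXTENDED_TABLE,
    STANDARD_TABLE,
    CTConversionTable,
    apply_override_policy,
    build_anthro_phantom,
    build_ic_phantom,
    build_patient_like,
    build_policy_structures,
    density_from_hu,
    hu_from_density,
    make_port,
    place_measurement_points,
    tld_packet_inventory,
)
from xpanderdose.geometry import rasterize_port
from xpanderdose.phantoms import add_metal_artifacts, anthro_port_center


class TestIcPhantom:
    def test_water_on_axis_away_from_port(self):
        build = build_ic_phantom(orientation="perpendicular", spacing=(2, 2, 2))
        idx = tuple(build.volume.world_to_index((0, 100, 0)).round().astype(int))
        assert build.volume.values[idx] == 1.0

    def test_port_voxel_has_calibrated_density(self):
        build = build_ic_phantom(orientation="perpendicular", spacing=(1, 1, 1))
        idx = tuple(build.volume.world_to_index((0, 52.5, 0)).round().astype(int))
        assert build.volume.values[idx] == 7.5

    def test_port_top_face_5cm_below_surface(self):
        perp = build_ic_phantom(orientation="perpendicular")
        assert perp.port.center[1] - perp.port.thickness / 2 == pytest.approx(50.0)
        par = build_ic_phantom(orientation="parallel")
        assert par.port.center[1] - par.port.diameter / 2 == pytest.approx(50.0)

    def test_metadata_records_the_measurement_setup(self):
        meta = build_ic_phantom().metadata
        assert meta["ssd_mm"] == 850.0
        assert meta["isocenter_depth_mm"] == 150.0
        assert meta["field_mm"] == (100.0, 100.0)
        assert meta["sample_depths_mm"][0] == 70.0 and meta["sample_depths_mm"][-1] == 150.0

    def test_orientations_differ_only_by_port_pose(self):
        kwargs = dict(spacing=(0.25, 0.25, 0.25), lateral_mm=40, depth_mm=200)
        perp = build_ic_phantom(orientation="perpendicular", **kwargs)
        par = build_ic_phantom(orientation="parallel", **kwargs)
        n_perp = (perp.volume.values > 1.5).sum()
        n_par = (par.volume.values > 1.5).sum()
        assert abs(n_perp - n_par) / n_perp < 0.01

    def test_shallow_grid_rejected(self):
        with pytest.raises(ValueError):
            build_ic_phantom(depth_mm=150.0)


class TestAnthroPhantom:
    def test_column_above_port_center_is_20mm(self):
        for state in ("inflated", "deflated"):
            build = build_anthro_phantom(state)
            surface = build.metadata["surface_x_mm"]
            assert surface - build.port.center[0] == pytest.approx(20.0)

    def test_block_thicknesses(self):
        assert build_anthro_phantom("inflated").metadata["block_mm"] == 63.0
        assert build_anthro_phantom("deflated").metadata["block_mm"] == 20.0

    def test_lung_voxel_density_round_trip(self):
        build = build_anthro_phantom("inflated", spacing=(2, 2, 2.5))
        idx = tuple(build.volume.world_to_index((-40, 0, 30)).round().astype(int))
        assert build.volume.values[idx] == pytest.approx(0.30)

    def test_ssd_metadata(self):
        assert build_anthro_phantom("inflated").metadata["ssd_mm"] == 907.0
        assert build_anthro_phantom("deflated").metadata["ssd_mm"] == 950.0

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            build_anthro_phantom("half-full")


class TestMeasurementPoints:
    @pytest.mark.parametrize("state", ["inflated", "deflated"])
    def test_four_points(self, state):
        assert len(place_measurement_points(state).points) == 4

    def test_points_1_2_4_at_25mm_from_port_center(self):
        center = np.array(anthro_port_center("inflated"))
        ms = place_measurement_points("inflated")
        for label in ("point1", "point2", "point4"):
            pos = np.array(ms.point(label).position_mm)
            assert np.linalg.norm(pos - center) == pytest.approx(25.0)

    def test_point3_on_beam_axis_under_port(self):
        center = np.array(anthro_port_center("deflated"))
        pos = np.array(place_measurement_points("deflated").point("point3").position_mm)
        # zero lateral offset from the beam-side axis through the port center
        assert pos[1] == pytest.approx(center[1]) and pos[2] == pytest.approx(center[2])
        assert pos[0] < center[0]  # downstream, "directly under"

    def test_tld_inventory_counts(self):
        inv = tld_packet_inventory()
        assert len(inv) == 28
        assert (inv.role == "measurement").sum() == 24
        assert (inv.role == "background").sum() == 1
        assert (inv.role == "calibration").sum() == 3


class TestArtifacts:
    @pytest.fixture
    def hu_build(self):
        return build_ic_phantom(orientation="perpendicular", spacing=(2, 2, 2), unit="HU")

    def test_zero_magnitude_is_identity(self, hu_build):
        mask = rasterize_port(hu_build.port, hu_build.volume)
        out = add_metal_artifacts(hu_build.volume, mask, magnitude_hu=0.0, seed=1)
        np.testing.assert_array_equal(out.values, hu_build.volume.values)

    def test_same_seed_identical(self, hu_build):
        mask = rasterize_port(hu_build.port, hu_build.volume)
        a = add_metal_artifacts(hu_build.volume, mask, seed=7)
        b = add_metal_artifacts(hu_build.volume, mask, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_amplitude_bounded_and_far_voxels_untouched(self, hu_build):
        mask = rasterize_port(hu_build.port, hu_build.volume)
        out = add_metal_artifacts(hu_build.volume, mask, magnitude_hu=300.0, seed=2)
        delta = np.abs(out.values - hu_build.volume.values)
        assert delta.max() <= 300.0 + 1e-9
        xs = hu_build.volume.axis_coords(0)
        far = np.abs(xs) > 80.0
        if far.any():
            assert delta[far].max() == 0.0

    def test_streaks_decay_with_distance(self, hu_build):
        mask = rasterize_port(hu_build.port, hu_build.volume)
        out = add_metal_artifacts(hu_build.volume, mask, magnitude_hu=300.0, seed=3)
        delta = np.abs(out.values - hu_build.volume.values)
        xs, ys = hu_build.volume.axis_coords(0), hu_build.volume.axis_coords(1)
        gx, gy = np.meshgrid(xs, ys - hu_build.port.center[1], indexing="ij")
        r = np.hypot(gx, gy)[:, :, None] * np.ones_like(delta)
        near = delta[(r < 20.0)].mean()
        far = delta[(r >= 50.0) & (r <= 80.0)].mean()
        assert near > far

    def test_density_volume_rejected(self):
        build = build_ic_phantom(spacing=(2, 2, 2))
        mask = rasterize_port(build.port, build.volume)
        with pytest.raises(ValueError):
            add_metal_artifacts(build.volume, mask, seed=0)


class TestConversionTable:
    def test_water_anchor(self):
        assert density_from_hu(EXTENDED_TABLE, 0.0) == 1.0

    def test_non_extended_table_saturates(self):
        assert density_from_hu(STANDARD_TABLE, 50_000.0) == 3.0

    def test_extended_round_trip_at_port_density(self):
        assert density_from_hu(EXTENDED_TABLE, hu_from_density(EXTENDED_TABLE, 7.5)) == pytest.approx(7.5)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            CTConversionTable(breakpoints=())
        with pytest.raises(ValueError):
            CTConversionTable(breakpoints=((0, 1.0), (0, 2.0)), extended=False)
        with pytest.raises(ValueError):
            CTConversionTable(breakpoints=((0, 1.0), (100, 0.5)), extended=False)


class TestOverridePolicies:
    @pytest.fixture
    def hu_build(self):
        return build_ic_phantom(orientation="perpendicular", spacing=(2, 2, 2), unit="HU")

    def test_new_policy_disk_density(self, hu_build):
        structures = build_policy_structures(hu_build.port, hu_build.volume, "new")
        out = apply_override_policy(hu_build.volume, structures, "new")
        from xpanderdose.geometry import rasterize

        roi_mask = rasterize(structures["port"], hu_build.volume)
        assert roi_mask.any()
        assert np.all(out.values[roi_mask] == 7.5)

    def test_clinical1_nominal_densities(self, hu_build):
        structures = build_policy_structures(hu_build.port, hu_build.volume, "clinical1")
        out = apply_override_policy(hu_build.volume, structures, "clinical1")
        assert 7.4 in out.values
        assert 4.2 in out.values

    def test_clinical2_saturated_port_density(self, hu_build):
        structures = build_policy_structures(hu_build.port, hu_build.volume, "clinical2")
        out = apply_override_policy(hu_build.volume, structures, "clinical2")
        mask = rasterize_port(hu_build.port, hu_build.volume)
        assert out.values[mask].max() == pytest.approx(3.0)

    def test_artifact_region_becomes_water(self, hu_build):
        art = add_metal_artifacts(
            hu_build.volume, rasterize_port(hu_build.port, hu_build.volume), seed=4
        )
        structures = build_policy_structures(hu_build.port, hu_build.volume, "new")
        out = apply_override_policy(art, structures, "new")
        from xpanderdose.geometry import rasterize

        artifact_mask = rasterize(structures["artifact"], hu_build.volume)
        port_mask = rasterize(structures["port"], hu_build.volume)
        assert np.all(out.values[artifact_mask & ~port_mask] == 1.0)

    def test_voxels_outside_rois_untouched(self, hu_build):
        structures = build_policy_structures(hu_build.port, hu_build.volume, "new")
        out = apply_override_policy(hu_build.volume, structures, "new")
        from xpanderdose.geometry import rasterize

        touched = rasterize(structures, hu_build.volume)
        base = np.asarray(density_from_hu(EXTENDED_TABLE, hu_build.volume.values))
        np.testing.assert_array_equal(out.values[~touched], base[~touched])

    def test_idempotent_on_density_output(self):
        build = build_ic_phantom(orientation="perpendicular", spacing=(2, 2, 2))
        for policy in ("clinical1", "new", "nodisk"):
            structures = build_policy_structures(build.port, build.volume, policy if policy != "nodisk" else "new")
            once = apply_override_policy(build.volume, structures, policy)
            twice = apply_override_policy(once, structures, policy)
            np.testing.assert_array_equal(once.values, twice.values)

    def test_missing_roi_rejected_by_name(self, hu_build):
        structures = build_policy_structures(hu_build.port, hu_build.volume, "new")
        with pytest.raises(ValueError, match="shell"):
            apply_override_policy(hu_build.volume, structures, "clinical1")

    def test_clinical2_requires_hu(self):
        build = build_ic_phantom(orientation="perpendicular", spacing=(2, 2, 2))
        structures = build_policy_structures(build.port, build.volume, "clinical2")
        with pytest.raises(ValueError, match="HU"):
            apply_override_policy(build.volume, structures, "clinical2")

    def test_artifact_pipeline_with_zero_magnitude_is_transparent(self, hu_build):
        mask = rasterize_port(hu_build.port, hu_build.volume)
        structures = build_policy_structures(hu_build.port, hu_build.volume, "new")
        plain = apply_override_policy(hu_build.volume, structures, "new")
        with_zero = apply_override_policy(
            add_metal_artifacts(hu_build.volume, mask, magnitude_hu=0.0, seed=9),
            structures,
            "new",
        )
        np.testing.assert_array_equal(plain.values, with_zero.values)


class TestPatientLike:
    def test_deterministic_per_seed(self):
        a = build_patient_like(seed=11)
        b = build_patient_like(seed=11)
        np.testing.assert_array_equal(a.volume.values, b.volume.values)
        c = build_patient_like(seed=12)
        assert not np.array_equal(a.volume.values, c.volume.values)

    def test_skin_points_deeper_than_1cm(self):
        build = build_patient_like(seed=3)
        wall_y = build.metadata["chest_wall_y_mm"]
        radius = build.metadata["body_radius_mm"]
        for label in ("skin1", "skin2"):
            pos = np.array(build.metadata["points"].point(label).position_mm)
            depth = radius - np.hypot(pos[0], pos[1] - wall_y)
            assert depth > 10.0

    def test_port_inside_dilated_expander(self):
        from scipy import ndimage

        build = build_patient_like(seed=3)
        masks = build.metadata["masks"]
        dilated = ndimage.binary_dilation(masks["expander"], iterations=1)
        assert np.all(dilated[masks["port"]])

    def test_volumes_finite_and_nonnegative(self):
        for build in (build_patient_like(seed=1), build_anthro_phantom("inflated"), build_ic_phantom()):
            assert np.all(np.isfinite(build.volume.values))
            assert np.all(build.volume.values >= 0)
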