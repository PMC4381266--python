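"""Aperture projection, PTV_PS construction and the surrogate SOBP dose."""

import numpy as np
import pytest

import straydose as sd
from straydose.proton import SOBPParams, _sobp_depth_dose
from conftest import sampled_pathlength


def small_water_grid(n=10, spacing=0.2):
    half = n * spacing / 2
    return sd.VoxelGrid(
        origin=[-half, -half, -half], spacing=[spacing] * 3, values=np.ones((n, n, n))
    )


def single_voxel_plan(grid, spacing):
    mask = np.zeros(grid.dims, dtype=bool)
    c = grid.dims[0] // 2
    mask[c, c, c] = True
    ptv = sd.StructureMask("ptv", mask, grid)
    plan = sd.BeamPlan(
        source=[0, 0, -233.0],
        axis=[0, 0, 1],
        collimator_plane_z=200.0,
        isocenter=grid.index_to_world(c, c, c),
        prescription=36.0,
    )
    plan.aperture = sd.project_aperture(ptv, plan, pixel=spacing / 10, pad=1.0)
    return ptv, plan


class TestProjectAperture:
    def test_sphere_projects_to_disc_by_similar_triangles(self, water_box_coarse):
        # 5 cm sphere seen from 233 cm with the collimator at 200 cm:
        # open disc diameter ~ 5 * 200/233 = 4.29 cm (+ voxel/pixel widening)
        aperture = water_box_coarse["plan"].aperture
        radius = aperture.max_open_radius()
        assert radius == pytest.approx(2.146, abs=0.45)
        open_area = aperture.open_pixel_count * aperture.spacing**2
        assert open_area == pytest.approx(np.pi * 2.146**2, rel=0.25)

    def test_single_voxel_opens_its_footprint_only(self):
        spacing = 0.2
        grid = small_water_grid(10, spacing)
        ptv, plan = single_voxel_plan(grid, spacing)
        aperture = plan.aperture
        open_area = aperture.open_pixel_count * aperture.spacing**2
        # projected voxel footprint: (0.2 * 200/233)^2, within pixelation
        expected = (spacing * 200.0 / 233.0) ** 2
        assert open_area == pytest.approx(expected, rel=0.35)

    def test_parallel_beam_limit_is_the_axial_silhouette(self, table):
        grid, target = sd.make_water_box(0.5)
        plan = sd.BeamPlan(
            source=[0, 0, -1e6],
            axis=[0, 0, 1],
            collimator_plane_z=1e6 - 33.0,
            isocenter=[0, 0, 0],
            prescription=36.0,
        )
        aperture = sd.project_aperture(target, plan, pixel=0.1)
        open_area = aperture.open_pixel_count * aperture.spacing**2
        silhouette = np.any(target.mask, axis=2).sum() * 0.5**2
        assert open_area == pytest.approx(silhouette, rel=0.1)

    def test_empty_ptv_rejected(self):
        grid = small_water_grid()
        ptv = sd.StructureMask("ptv", np.zeros(grid.dims, bool), grid)
        plan = sd.BeamPlan(
            source=[0, 0, -233.0],
            axis=[0, 0, 1],
            collimator_plane_z=200.0,
            isocenter=[0, 0, 0],
            prescription=36.0,
        )
        with pytest.raises(ValueError, match="empty PTV"):
            sd.project_aperture(ptv, plan)


class TestModulationWidth:
    def test_sphere_in_water_equals_diameter(self, water_box_coarse):
        assert water_box_coarse["plan"].modulation_width == pytest.approx(5.0, abs=1e-3)

    def test_scales_with_medium_density(self, table):
        grid, target = sd.make_water_box(0.5)
        half = sd.VoxelGrid(
            origin=grid.origin, spacing=grid.spacing, values=0.5 * grid.values
        )
        plan = sd.default_water_box_plan()
        plan.aperture = sd.project_aperture(target, plan)
        m = sd.modulation_width(target, half, table, plan)
        assert m == pytest.approx(2.5, abs=1e-3)

    def test_single_voxel_gives_voxel_thickness(self, table):
        spacing = 0.2
        grid = small_water_grid(10, spacing)
        ptv, plan = single_voxel_plan(grid, spacing)
        assert sd.modulation_width(ptv, grid, table, plan) == pytest.approx(0.2, abs=1e-6)

    def test_per_ray_not_larger_than_global(self, water_box_coarse, table):
        wb = water_box_coarse
        per_ray = sd.modulation_width(
            wb["target"], wb["grid"], table, wb["plan"], per_ray=True
        )
        assert per_ray <= wb["plan"].modulation_width + 1e-9


class TestBuildPtvPs:
    def test_contains_ptv_in_homogeneous_medium(self, water_box_coarse):
        wb = water_box_coarse
        assert np.all(wb["ptv_ps"].mask[wb["target"].mask])

    def test_per_ray_thickness_matches_modulation(self, water_box_coarse, table):
        # central-axis column of PTV_PS spans the modulation width in water
        wb = water_box_coarse
        grid = wb["grid"]
        c = grid.dims[0] // 2
        column = wb["ptv_ps"].mask[c, c, :]
        thickness = column.sum() * grid.spacing[2]
        assert thickness == pytest.approx(wb["plan"].modulation_width, abs=2 * grid.spacing[2])

    def test_zero_modulation_gives_distal_shell(self, table):
        grid, target = sd.make_water_box(0.5)
        plan = sd.default_water_box_plan()
        plan.aperture = sd.project_aperture(target, plan)
        plan.modulation_width = 0.0
        shell = sd.build_ptv_ps(target, grid, table, plan)
        assert shell.voxel_count > 0
        # a thin shell: far fewer voxels than the target, and no more than
        # two per grid column (divergent rays can split a column over two
        # adjacent beam's-eye pixels)
        assert shell.voxel_count < 0.5 * target.voxel_count
        assert shell.mask.sum(axis=2).max() <= 2
        # the shell hugs the distal target hemisphere (z >= sphere center,
        # give or take rim voxels split across beam's-eye pixels)
        idx = np.argwhere(shell.mask)
        zc = grid.origin[2] + (idx[:, 2] + 0.5) * grid.spacing[2]
        assert np.median(zc) >= 0.0
        assert zc.min() >= -4 * grid.spacing[2]

    def test_single_voxel_ptv_maps_to_itself(self, table):
        spacing = 0.2
        grid = small_water_grid(10, spacing)
        ptv, plan = single_voxel_plan(grid, spacing)
        plan.modulation_width = sd.modulation_width(ptv, grid, table, plan)
        ps = sd.build_ptv_ps(ptv, grid, table, plan)
        assert np.array_equal(ps.mask, ptv.mask)

    def test_geometry_mismatch_rejected(self, water_box_coarse, table):
        wb = water_box_coarse
        other = sd.VoxelGrid(
            origin=wb["grid"].origin + 1.0,
            spacing=wb["grid"].spacing,
            values=wb["grid"].values,
        )
        with pytest.raises(ValueError, match="geometries differ"):
            sd.build_ptv_ps(wb["target"], other, table, wb["plan"])


class TestProtonDose:
    def test_mean_target_dose_near_prescription(self, water_box_coarse):
        wb = water_box_coarse
        mean = wb["dose"].values[wb["target"].mask].mean()
        assert 0.99 <= mean / 36.0 <= 1.01

    def test_isocenter_dose_equals_prescription(self, water_box_coarse):
        wb = water_box_coarse
        ic = wb["dose"].values[wb["grid"].world_to_index([0, 0, 0])]
        assert ic == pytest.approx(36.0, rel=5e-3)

    def test_lateral_falloff_three_cm_outside_field(self, water_box_coarse):
        wb = water_box_coarse
        grid = wb["grid"]
        r_edge = wb["plan"].aperture.max_open_radius() * 233.0 / 200.0
        for ang in np.linspace(0, 2 * np.pi, 24):
            x = (r_edge + 3.0) * np.cos(ang)
            y = (r_edge + 3.0) * np.sin(ang)
            val = wb["dose"].values[grid.world_to_index([x, y, 0])]
            assert val / 36.0 <= 1e-5

    def test_distal_falloff_within_one_cm(self, water_box_coarse):
        wb = water_box_coarse
        grid = wb["grid"]
        c = grid.dims[0] // 2
        iz = grid.world_to_index([0, 0, 3.5])[2]  # 1 cm beyond the distal edge
        assert wb["dose"].values[c, c, iz] / 36.0 < 1e-5

    def test_dose_bounded_by_prescription(self, water_box_coarse):
        vals = water_box_coarse["dose"].values
        assert vals.min() >= 0
        assert vals.max() <= 1.05 * 36.0

    def test_zero_beyond_lateral_cutoff(self, water_box_coarse):
        wb = water_box_coarse
        sdist = wb["diag"]["signed_distance_coll"]
        far = sdist >= SOBPParams().lateral_cutoff
        assert np.all(wb["dose"].values[far] == 0)

    def test_depth_dose_matches_closed_form_on_random_rays(self, water_box_coarse, table):
        """In homogeneous water the per-voxel dose in the field core equals
        prescription * SOBP(depth) with the engine's own per-ray range."""
        wb = water_box_coarse
        grid, plan = wb["grid"], wb["plan"]
        params = SOBPParams()
        rng = np.random.default_rng(11)
        # sample rays well inside the aperture (penumbra ~ 1) and upstream of
        # the distal falloff, where the profile slope is shallow
        iz_max = grid.world_to_index([0, 0, 2.0])[2]
        for _ in range(50):
            x, y = rng.uniform(-1.2, 1.2, 2)
            iz = rng.integers(0, iz_max)
            i, j, _ = grid.world_to_index([x, y, 0])
            center = grid.index_to_world(i, j, iz)
            depth = sampled_pathlength(grid, plan.source, center, step=0.01)
            rngmap = wb["diag"]["range_map"]
            aperture = plan.aperture
            # aperture pixel of this voxel's own ray, in the beam's (u, v) basis
            u, v, ax = sd.beam_basis(plan.axis)
            rel = center - plan.source
            scale = plan.collimator_plane_z / (rel @ ax)
            iu = int(np.floor(((rel @ u) * scale - aperture.origin[0]) / aperture.spacing))
            iv = int(np.floor(((rel @ v) * scale - aperture.origin[1]) / aperture.spacing))
            expected = 36.0 * _sobp_depth_dose(depth, rngmap[iu, iv], plan.modulation_width, params)
            got = wb["dose"].values[i, j, iz]
            assert got == pytest.approx(expected, rel=2e-3, abs=2e-3)

    def test_empty_ptv_ps_rejected(self, water_box_coarse, table):
        wb = water_box_coarse
        empty = sd.StructureMask("ptv_ps", np.zeros(wb["grid"].dims, bool), wb["grid"])
        with pytest.raises(ValueError, match="PTV_PS"):
            sd.proton_dose_grid(wb["plan"], wb["grid"], table, empty)

    def test_isocenter_outside_grid_rejected(self, water_box_coarse, table):
        import dataclasses

        wb = water_box_coarse
        plan = dataclasses.replace(wb["plan"], isocenter=[0, 0, 100.0])
        plan.aperture = wb["plan"].aperture
        plan.modulation_width = wb["plan"].modulation_width
        with pytest.raises(ValueError, match="isocenter"):
            sd.proton_dose_grid(plan, wb["grid"], table, wb["ptv_ps"])
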