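import numpy as np
import pytest
from scipy import ndimage

from mwaplan.manufacturer import EllipsoidSpec, ellipsoid_mask
from mwaplan.metrics import (
    dice,
    evaluate_case,
    signed_surface_distances,
    vascular_fraction,
)
from mwaplan.volumes import AblationSetting, ApplicatorPose, LabelVolume, VoxelGrid


def mask_from(grid, voxels, role="ablation_pred"):
    return LabelVolume(grid=grid, voxels=voxels, role=role)


class TestDice:
    def test_identical_nonempty_masks(self, sphere_factory):
        grid = VoxelGrid(shape=(16, 16, 16))
        a = sphere_factory(grid, grid.center(), 5.0)
        assert dice(a, a) == 1.0

    def test_disjoint_masks(self):
        grid = VoxelGrid(shape=(16, 16, 16))
        va = np.zeros(grid.shape, dtype=bool); va[:4] = True
        vb = np.zeros(grid.shape, dtype=bool); vb[10:] = True
        assert dice(mask_from(grid, va), mask_from(grid, vb)) == 0.0

    def test_half_overlap_direct_formula(self):
        grid = VoxelGrid(shape=(8, 8, 8))
        va = np.zeros(grid.shape, dtype=bool); va[0, 0, :8] = True
        vb = np.zeros(grid.shape, dtype=bool); vb[0, 0, 4:] = True
        vb[0, 1, :4] = True
        assert dice(mask_from(grid, va), mask_from(grid, vb)) == 0.5

    def test_both_empty_convention(self):
        grid = VoxelGrid(shape=(4, 4, 4))
        empty = mask_from(grid, np.zeros(grid.shape, dtype=bool))
        assert dice(empty, empty) == 1.0

    def test_symmetry_and_brute_force_on_random_masks(self):
        grid = VoxelGrid(shape=(16, 16, 16))
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = mask_from(grid, rng.random(grid.shape) > 0.7)
            b = mask_from(grid, rng.random(grid.shape) > 0.7)
            sa = {tuple(i) for i in np.argwhere(a.voxels)}
            sb = {tuple(i) for i in np.argwhere(b.voxels)}
            expected = 2 * len(sa & sb) / (len(sa) + len(sb))
            assert dice(a, b) == pytest.approx(expected, rel=1e-12)
            assert dice(b, a) == dice(a, b)

    def test_grid_mismatch_rejected(self):
        a = mask_from(VoxelGrid(shape=(8, 8, 8)), np.ones((8, 8, 8), dtype=bool))
        b = mask_from(VoxelGrid(shape=(9, 9, 9)), np.ones((9, 9, 9), dtype=bool))
        with pytest.raises(ValueError):
            dice(a, b)


class TestSignedSurfaceDistances:
    def test_identity_gives_zero_everywhere(self, sphere_factory):
        grid = VoxelGrid(shape=(24, 24, 24))
        m = sphere_factory(grid, grid.center(), 8.0)
        signed, hausdorff, stats = signed_surface_distances(m, m)
        assert hausdorff == 0.0
        assert stats.mean_mm == 0.0

    def test_concentric_spheres_positive_gap(self, sphere_factory):
        grid = VoxelGrid(shape=(32, 32, 32))
        pred = sphere_factory(grid, grid.center(), 10.0)
        gt = sphere_factory(grid, grid.center(), 6.0)
        signed, hausdorff, stats = signed_surface_distances(pred, gt)
        assert np.all(signed > 0)  # ground truth enclosed by prediction
        assert stats.mean_mm == pytest.approx(4.0, abs=1.0)
        assert hausdorff == pytest.approx(4.0, abs=1.0)

    def test_gt_containing_pred_all_negative(self, sphere_factory):
        grid = VoxelGrid(shape=(32, 32, 32))
        pred = sphere_factory(grid, grid.center(), 6.0)
        gt = sphere_factory(grid, grid.center(), 10.0)
        signed, _, _ = signed_surface_distances(pred, gt)
        assert np.all(signed < 0)

    def test_sign_antisymmetry_under_swap(self, sphere_factory):
        grid = VoxelGrid(shape=(32, 32, 32))
        a = sphere_factory(grid, grid.center(), 10.0)
        b = sphere_factory(grid, grid.center(), 7.0)
        s_ab, h_ab, _ = signed_surface_distances(a, b)
        s_ba, h_ba, _ = signed_surface_distances(b, a)
        assert np.mean(s_ab) == pytest.approx(-np.mean(s_ba), abs=1.0)
        assert h_ab == pytest.approx(h_ba, abs=1.0)

    def test_empty_mask_rejected(self, sphere_factory):
        grid = VoxelGrid(shape=(16, 16, 16))
        full = sphere_factory(grid, grid.center(), 5.0)
        empty = mask_from(grid, np.zeros(grid.shape, dtype=bool))
        with pytest.raises(ValueError):
            signed_surface_distances(full, empty)

    def test_anisotropic_spacing_measured_in_mm(self):
        grid = VoxelGrid(shape=(20, 20, 20), spacing=(1.0, 1.0, 2.0))
        va = np.zeros(grid.shape, dtype=bool); va[4:16, 4:16, 8:12] = True
        vb = np.zeros(grid.shape, dtype=bool); vb[4:16, 4:16, 7:13] = True
        # gt extends one 2 mm voxel beyond pred along z; slab wide enough that
        # central face voxels are governed by the z gap, not the side faces
        signed, hausdorff, _ = signed_surface_distances(mask_from(grid, va), mask_from(grid, vb))
        assert hausdorff == pytest.approx(2.0, abs=0.01)
        assert np.all(signed <= 0)


class TestVascularFraction:
    def _spec(self, grid):
        return EllipsoidSpec(center=tuple(grid.center()), long_axis_direction=(1, 0, 0),
                             length=30.0, diameter=20.0)

    def test_no_vessels_zero(self):
        grid = VoxelGrid(shape=(40, 40, 40))
        vessels = mask_from(grid, np.zeros(grid.shape, dtype=bool), "vessel")
        assert vascular_fraction(vessels, self._spec(grid), grid) == 0.0

    def test_vessels_cover_everything_one(self):
        grid = VoxelGrid(shape=(40, 40, 40))
        vessels = mask_from(grid, np.ones(grid.shape, dtype=bool), "vessel")
        assert vascular_fraction(vessels, self._spec(grid), grid) == 1.0

    def test_cylinder_through_center_matches_set_oracle(self):
        grid = VoxelGrid(shape=(40, 40, 40))
        spec = self._spec(grid)
        c = grid.center()
        x, y, z = grid.coordinate_arrays()
        cyl = ((y - c[1]) ** 2 + (z - c[2]) ** 2) <= 2.0**2
        vessels = mask_from(grid, np.broadcast_to(cyl, grid.shape).copy(), "vessel")
        emask = ellipsoid_mask(spec, grid)
        oracle = int((vessels.voxels & emask.voxels).sum()) / emask.n_true
        assert vascular_fraction(vessels, spec, grid) == pytest.approx(oracle, rel=1e-12)


class TestEvaluateCase:
    def test_perfect_prediction(self, sphere_factory, table):
        grid = VoxelGrid(shape=(32, 32, 32))
        pred = sphere_factory(grid, grid.center(), 9.0)
        gt = sphere_factory(grid, grid.center(), 9.0, role="ablation_gt")
        vessels = mask_from(grid, np.zeros(grid.shape, dtype=bool), "vessel")
        pose = ApplicatorPose(tip=tuple(grid.center() + np.array([10.0, 0, 0])),
                              direction=(1.0, 0.0, 0.0))
        plan = [(pose, AblationSetting.from_minutes(90.0, 5.0))]
        m = evaluate_case(pred, gt, vessels, table, plan)
        assert m.dice == 1.0
        assert m.hausdorff_mm == 0.0
        assert m.rel_vol_diff == 0.0
        assert m.vascular_fraction == 0.0

    def test_dilated_gt_one_voxel(self, sphere_factory):
        grid = VoxelGrid(shape=(32, 32, 32))
        pred = sphere_factory(grid, grid.center(), 8.0)
        dil = ndimage.binary_dilation(
            pred.voxels, structure=ndimage.generate_binary_structure(3, 1)
        )
        gt = mask_from(grid, dil, "ablation_gt")
        m = evaluate_case(pred, gt)
        assert m.hausdorff_mm == pytest.approx(1.0, abs=0.5)
        signed, _, stats = signed_surface_distances(pred, gt)
        assert np.all(signed <= 0)

    def test_rel_vol_diff_formula(self, sphere_factory):
        grid = VoxelGrid(shape=(32, 32, 32))
        pred = sphere_factory(grid, grid.center(), 6.0)
        gt = sphere_factory(grid, grid.center(), 8.0, role="ablation_gt")
        m = evaluate_case(pred, gt)
        expected = abs(pred.volume_ml - gt.volume_ml) / gt.volume_ml
        assert m.rel_vol_diff == pytest.approx(expected, rel=1e-12)

    def test_vascular_fraction_is_max_over_sequential_ablations(self, table):
        grid = VoxelGrid(shape=(96, 96, 96))
        c = grid.center()
        x, y, z = grid.coordinate_arrays()
        # vessel cylinder near the first ablation only
        cyl = ((y - c[1]) ** 2 + (z - (c[2] - 6.0)) ** 2) <= 3.0**2
        vessels = mask_from(grid, np.broadcast_to(cyl, grid.shape).copy(), "vessel")
        setting = AblationSetting.from_minutes(90.0, 5.0)
        near = ApplicatorPose(tip=tuple(c + np.array([10.0, 0, 0])), direction=(1.0, 0, 0))
        far = ApplicatorPose(tip=tuple(c + np.array([10.0, 30.0, 30.0])), direction=(1.0, 0, 0))
        pred = mask_from(grid, np.zeros(grid.shape, dtype=bool))
        pred.voxels[40:60, 40:60, 40:60] = True
        gt = mask_from(grid, pred.voxels.copy(), "ablation_gt")
        m_near_only = evaluate_case(pred, gt, vessels, table, [(near, setting)])
        m_both = evaluate_case(pred, gt, vessels, table, [(near, setting), (far, setting)])
        assert m_both.vascular_fraction == pytest.approx(m_near_only.vascular_fraction)
        assert m_both.vascular_fraction > 0
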