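"""Soft Gaussian targets, instance labels, MIP slicing and stitching."""

import numpy as np
import pytest

from somaloc.core import CellCenters
from somaloc.phantom import PhantomConfig, generate_centers
from somaloc.targets import (
    INSTANCE_THRESHOLD,
    KAPPA,
    compute_sigmas,
    make_mip_slices,
    render_soft_mask,
    soft_to_instance,
    stitch_planewise_masks,
    support_radius,
)


class TestComputeSigmas:
    def test_isolated_cell_gets_upper_bound(self):
        sig = compute_sigmas(CellCenters([[10.0, 10.0, 10.0]]))
        np.testing.assert_allclose(sig, 3.5)

    @pytest.mark.parametrize(
        "distance,expected",
        [(4.0, 1.0), (16.0, 16.0 / KAPPA), (40.0, 3.5)],
        ids=["clipped-low", "interior", "clipped-high"],
    )
    def test_nearest_neighbour_formula(self, distance, expected):
        c = CellCenters([[10.0, 10.0, 10.0], [10.0, 10.0, 10.0 + distance]])
        sig = compute_sigmas(c)
        np.testing.assert_allclose(sig, expected)
        if distance == 16.0:
            # kappa = 6.3975..., so 16/kappa prints as 2.5
            np.testing.assert_allclose(sig[0, 0], 2.5, atol=2e-3)

    def test_anisotropy_rescales_axes(self):
        c = CellCenters([[10.0, 10.0, 10.0]])
        sig = compute_sigmas(c, anisotropy=(2.0, 1.0, 1.0))
        np.testing.assert_allclose(sig[0], [7.0, 3.5, 3.5])

    def test_empty_centers_raise(self):
        with pytest.raises(ValueError):
            compute_sigmas(CellCenters(np.empty((0, 3))))


class TestRenderSoftMask:
    def test_peak_is_one_at_center(self):
        soft = render_soft_mask(CellCenters([[8.0, 8.0, 8.0]]), [2.0], (16, 16, 16))
        assert soft.data[8, 8, 8] == pytest.approx(1.0)

    def test_two_sigma_value(self):
        soft = render_soft_mask(CellCenters([[16.0, 16.0, 16.0]]), [3.0], (32, 32, 32))
        assert soft.data[16, 16, 22] == pytest.approx(np.exp(-2.0), rel=1e-6)

    def test_support_radius_closed_form(self):
        assert support_radius(1.0) == pytest.approx(np.sqrt(2 * np.log(1 / 0.006)))
        assert support_radius(2.0) == pytest.approx(2 * 3.199, abs=2e-3)

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(5, 27, size=(6, 3))
        sig = rng.uniform(1, 3, size=6)
        a = render_soft_mask(CellCenters(pts), sig, (32, 32, 32)).data
        perm = rng.permutation(6)
        b = render_soft_mask(CellCenters(pts[perm]), sig[perm], (32, 32, 32)).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_overlap_combined_by_maximum(self):
        c = CellCenters([[8.0, 8.0, 7.0], [8.0, 8.0, 9.0]])
        soft = render_soft_mask(c, [2.0, 2.0], (16, 16, 16))
        assert soft.data.max() <= 1.0 + 1e-12
        assert soft.data[8, 8, 7] == pytest.approx(1.0)


class TestSoftToInstance:
    def test_all_zero_gives_no_instances(self):
        labels = soft_to_instance(np.zeros((8, 8, 8)))
        assert labels.max() == 0

    def test_distant_gaussians_stay_separate(self):
        c = CellCenters([[10.0, 10.0, 5.0], [10.0, 10.0, 45.0]])
        soft = render_soft_mask(c, [2.0, 2.0], (20, 20, 50))
        labels = soft_to_instance(soft)
        assert labels.max() == 2

    def test_component_volume_matches_support_sphere(self):
        # one sigma=2 Gaussian: support radius 3.199*2, volume (4/3)pi r^3
        soft = render_soft_mask(CellCenters([[24.0, 24.0, 24.0]]), [2.0], (48, 48, 48))
        labels = soft_to_instance(soft)
        count = np.count_nonzero(labels == 1)
        expected = 4 / 3 * np.pi * (support_radius(2.0)) ** 3
        assert abs(count - expected) < 0.1 * expected

    def test_hard_core_phantom_recovers_one_instance_per_cell(self):
        # separation 25 voxels > 2*3.199*sigma_max = 22.4 keeps supports
        # strictly disjoint (tangent spheres would bridge on the grid)
        cfg = PhantomConfig(
            shape=(80, 80, 80), density=800, min_separation_um=25 * 3.6,
            seed=11,
        )
        centers = generate_centers(cfg)
        sig = compute_sigmas(centers)
        soft = render_soft_mask(centers, sig, cfg.shape)
        labels = soft_to_instance(soft)
        assert labels.max() == len(centers)
        # centroid check only where the support sphere is not clipped by the
        # volume border (clipping shifts the centroid along the cut axis)
        margin = 3.2 * 3.5
        checked = 0
        for k in range(1, labels.max() + 1):
            centroid = np.argwhere(labels == k).mean(axis=0)
            i = np.linalg.norm(centers.points - centroid, axis=1).argmin()
            c = centers.points[i]
            if np.all(c >= margin) and np.all(c < 80 - margin):
                assert np.linalg.norm(c - centroid) <= 1.0
                checked += 1
        assert checked >= 3


class TestMipSlices:
    def test_constant_volume_projects_to_constant(self):
        slices = make_mip_slices(np.full((5, 4, 4), 7.0))
        assert len(slices) == 5
        for s in slices:
            np.testing.assert_allclose(s, 7.0)

    def test_bright_voxel_window_arithmetic(self):
        vol = np.zeros((20, 8, 8))
        vol[10, 3, 3] = 1.0
        slices = make_mip_slices(vol, window=9)
        hit = [i for i, s in enumerate(slices) if s.max() == 1.0]
        assert hit == list(range(6, 15))  # 10 +/- 4 inclusive

    def test_depth_one_volume(self):
        vol = np.arange(16, dtype=float).reshape(1, 4, 4)
        slices = make_mip_slices(vol)
        assert len(slices) == 1
        np.testing.assert_array_equal(slices[0], vol[0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            make_mip_slices(np.zeros((4, 4, 4)), window=8)


def disc_mask(shape, cy, cx, r, label=1):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2, label, 0)


class TestStitchPlanewise:
    def test_identical_disc_merges_to_one_instance(self):
        disc = disc_mask((20, 20), 10, 10, 4)
        labels, centers = stitch_planewise_masks([disc] * 5)
        assert labels.max() == 1
        np.testing.assert_allclose(centers.points[0][0], 2.0)  # middle plane
        np.testing.assert_allclose(centers.points[0][1:], [10.0, 10.0], atol=0.5)

    def test_gap_plane_splits_instances(self):
        disc = disc_mask((16, 16), 8, 8, 3)
        empty = np.zeros((16, 16), dtype=int)
        labels, centers = stitch_planewise_masks([disc, empty, disc])
        assert labels.max() == 2

    def test_iou_just_above_threshold_merges(self):
        # two 10x10 squares offset by 5 columns: IOU = 50/150 = 1/3 > 0.3
        a = np.zeros((20, 30), dtype=int)
        b = np.zeros((20, 30), dtype=int)
        a[5:15, 5:15] = 1
        b[5:15, 10:20] = 1
        labels, centers = stitch_planewise_masks([a, b])
        assert labels.max() == 1

    def test_iou_below_threshold_stays_split(self):
        a = np.zeros((20, 30), dtype=int)
        b = np.zeros((20, 30), dtype=int)
        a[5:15, 5:15] = 1
        b[5:15, 12:22] = 1  # IOU = 30/170 < 0.3
        labels, centers = stitch_planewise_masks([a, b])
        assert labels.max() == 2

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            stitch_planewise_masks([np.zeros((4, 4)), np.zeros((5, 5))])

    def test_sliced_3d_instance_count_is_preserved(self):
        # trivially slicing a 3-D instance mask and re-stitching it keeps K
        vol = np.zeros((6, 24, 24), dtype=int)
        vol[1:5, 4:10, 4:10] = 1
        vol[2:5, 14:20, 14:20] = 2
        labels, centers = stitch_planewise_masks([vol[z] for z in range(6)])
        assert labels.max() == 2
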