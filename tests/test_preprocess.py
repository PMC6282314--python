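import numpy as np
import pytest

import alphacomplexity as ac
from alphacomplexity.preprocess import BinaryVolume

from _oracles import fill_2d_oracle


def bvol(grid, vox=1.0):
    return BinaryVolume(np.asarray(grid, dtype=bool), vox)


class TestBinarize:
    def test_bimodal_stack_splits_on_modes(self, rng):
        lo = rng.normal(50, 5, size=(4, 16, 16))
        hi = rng.normal(200, 5, size=(4, 16, 16))
        take_hi = rng.random((4, 16, 16)) > 0.5
        stack = np.where(take_hi, hi, lo).astype(np.uint8)
        vol = ac.binarize(stack, 1.0)
        assert np.array_equal(vol.grid, take_hi)

    def test_two_valued_stack_passes_through(self):
        stack = np.zeros((2, 4, 4), dtype=np.uint8)
        stack[0, :2] = 255
        vol = ac.binarize(stack, 1.0)
        assert np.array_equal(vol.grid, stack == 255)

    def test_boolean_stack_is_identity(self):
        stack = np.zeros((2, 4, 4), dtype=bool)
        stack[1, 1, 1] = True
        assert np.array_equal(ac.binarize(stack, 1.0).grid, stack)

    def test_constant_stack_rejected(self):
        with pytest.raises(ac.EmptyForeground):
            ac.binarize(np.zeros((2, 4, 4), dtype=np.uint8), 1.0)


class TestCloseSlices:
    def test_bridges_contour_gap(self):
        # annulus with a 4-px gap in one slice; radius-6 closing bridges it
        yy, xx = np.mgrid[:40, :40]
        rad = np.hypot(yy - 20, xx - 20)
        ring = (rad >= 12) & (rad < 15)
        ring[18:22, 30:] = False  # cut a gap through the contour
        vol = bvol(ring[None])
        closed = ac.close_slices(vol, 6)
        filled = ac.fill_holes(closed)
        # once bridged, the enclosed cavity is fillable
        assert filled.grid.sum() > closed.grid.sum() + 100

    def test_solid_convex_slice_unchanged(self):
        # a filled rectangle offers the structuring element no gap to close
        grid = np.zeros((1, 30, 30), dtype=bool)
        grid[0, 5:25, 8:22] = True
        vol = bvol(grid)
        assert np.array_equal(ac.close_slices(vol, 6).grid, vol.grid)

    def test_closing_is_idempotent(self):
        yy, xx = np.mgrid[:30, :30]
        disc = np.hypot(yy - 15, xx - 15) < 10
        once = ac.close_slices(bvol(disc[None]), 6)
        twice = ac.close_slices(once, 6)
        assert np.array_equal(once.grid, twice.grid)

    def test_radius_zero_is_identity(self, rng):
        grid = rng.random((3, 10, 10)) > 0.5
        vol = bvol(grid)
        assert np.array_equal(ac.close_slices(vol, 0).grid, grid)

    def test_negative_radius_rejected(self):
        with pytest.raises(ac.InvalidParameter):
            ac.close_slices(bvol(np.ones((1, 3, 3))), -1)


class TestFillHoles:
    def test_shell_fills_to_solid_ball(self):
        shell_spec = ac.ShapeSpec(
            kind="hollow_sphere", radius=10, shell_thickness=3, voxel_size_mm=1
        )
        ball_spec = ac.ShapeSpec(kind="sphere", radius=10, voxel_size_mm=1)
        filled = ac.fill_holes(ac.make_shape(shell_spec), mode="slice")
        assert filled.n_foreground == ac.make_shape(ball_spec).n_foreground

    def test_matches_bfs_oracle_per_slice(self, rng):
        grid = rng.random((3, 12, 12)) > 0.6
        filled = ac.fill_holes(bvol(grid))
        for i in range(3):
            assert np.array_equal(filled.grid[i], fill_2d_oracle(grid[i]))

    def test_idempotent(self, rng):
        grid = rng.random((4, 15, 15)) > 0.55
        once = ac.fill_holes(bvol(grid))
        twice = ac.fill_holes(once)
        assert np.array_equal(once.grid, twice.grid)

    def test_open_c_shape_untouched(self):
        c = np.zeros((1, 9, 9), dtype=bool)
        c[0, 1:8, 1:3] = True
        c[0, 1:3, 1:8] = True
        c[0, 6:8, 1:8] = True  # open towards the right edge
        filled = ac.fill_holes(bvol(c))
        assert np.array_equal(filled.grid, c)

    def test_3d_mode_closes_sealed_cavity_keeps_canal(self):
        grid = np.ones((7, 7, 7), dtype=bool)
        grid[3, 3, 3] = False  # sealed cavity
        filled = ac.fill_holes(bvol(grid), mode="3d")
        assert filled.grid[3, 3, 3]
        canal = np.ones((7, 7, 7), dtype=bool)
        canal[:, 3, 3] = False  # through-going canal along the slice axis
        assert not ac.fill_holes(bvol(canal), mode="3d").grid[:, 3, 3].any()


class TestRawVolumeAndCloud:
    def test_raw_volume_arithmetic(self):
        grid = np.zeros((10, 10, 10), dtype=bool)
        grid.flat[:1000] = True
        assert ac.raw_volume(bvol(grid, 0.05)) == pytest.approx(0.125)
        single = np.zeros((1, 1, 1), dtype=bool)
        single[0, 0, 0] = True
        assert ac.raw_volume(bvol(single, 1.0)) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ac.EmptyForeground):
            ac.raw_volume(bvol(np.zeros((2, 2, 2))))
        with pytest.raises(ac.EmptyForeground):
            ac.to_point_cloud(bvol(np.zeros((2, 2, 2))))

    def test_voxel_centre_convention(self):
        grid = np.zeros((3, 3, 3), dtype=bool)
        grid[:2, :2, :2] = True
        pc = ac.to_point_cloud(bvol(grid))
        assert pc.n_points == 8
        assert set(map(tuple, pc.coordinates)) == {
            (x, y, z) for x in (0.5, 1.5) for y in (0.5, 1.5) for z in (0.5, 1.5)
        }

    def test_interior_points_included(self):
        grid = np.ones((3, 3, 3), dtype=bool)
        assert ac.to_point_cloud(bvol(grid)).n_points == 27


class TestDownsample:
    def test_identity_when_n_equals_size(self, rng):
        pc = ac.PointCloud(rng.random((50, 3)))
        out = ac.downsample(pc, 50, seed=1)
        assert np.array_equal(out.coordinates, pc.coordinates)

    def test_deterministic_given_seed(self, rng):
        pc = ac.PointCloud(rng.random((500, 3)))
        a = ac.downsample(pc, 100, seed=42)
        b = ac.downsample(pc, 100, seed=42)
        assert np.array_equal(a.coordinates, b.coordinates)
        c = ac.downsample(pc, 100, seed=43)
        assert not np.array_equal(a.coordinates, c.coordinates)

    def test_subset_without_replacement(self, rng):
        pts = rng.random((200, 3))
        out = ac.downsample(ac.PointCloud(pts), 80, seed=0)
        as_set = set(map(tuple, pts))
        picked = list(map(tuple, out.coordinates))
        assert len(set(picked)) == 80
        assert set(picked) <= as_set

    def test_oversampling_rejected(self, rng):
        pc = ac.PointCloud(rng.random((10, 3)))
        with pytest.raises(ac.InvalidParameter):
            ac.downsample(pc, 11, seed=0)
        with pytest.raises(ac.InvalidParameter):
            ac.downsample(pc, 3, seed=0)
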