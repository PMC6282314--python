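import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import alphacomplexity as ac
from alphacomplexity.preprocess import PointCloud

from _oracles import bisect_k_star


class TestReferenceLengths:
    def test_bbox_diagonal_3_4_12(self):
        pc = np.array([[0, 0, 0], [3, 4, 12.0]])
        assert ac.ref_length_bbox(pc).value_mm == pytest.approx(13.0)

    def test_centroid_mean_pair(self):
        pc = np.array([[-1, 0, 0], [1, 0, 0.0]])
        assert ac.ref_length_centroid(pc).value_mm == pytest.approx(1.0)

    def test_centroid_translation_invariant(self, rng):
        pts = rng.random((60, 3))
        a = ac.ref_length_centroid(pts).value_mm
        b = ac.ref_length_centroid(pts + 17.0).value_mm
        assert a == pytest.approx(b, rel=1e-9)

    def test_knn_two_points(self):
        pc = np.array([[0, 0, 0], [0, 0, 2.5]])
        assert ac.ref_length_knn(pc, 1).value_mm == pytest.approx(2.5)

    def test_knn_collinear_chain(self):
        # chain 0,1,2,3 with k=2: per-point means (1.5, 1, 1, 1.5) -> 1.25
        pc = np.array([[i, 0, 0] for i in range(4)], dtype=float)
        assert ac.ref_length_knn(pc, 2).value_mm == pytest.approx(1.25)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(0.01, 50), seed=st.integers(0, 1000))
    def test_homogeneity_under_scaling(self, c, seed):
        pts = np.random.default_rng(seed).random((40, 3))
        for fn in (
            ac.ref_length_bbox,
            ac.ref_length_centroid,
            lambda p: ac.ref_length_knn(p, 5),
        ):
            assert fn(c * pts).value_mm == pytest.approx(c * fn(pts).value_mm, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        dup = np.zeros((2, 3))
        with pytest.raises(ac.InvalidParameter):
            ac.ref_length_bbox(dup)
        with pytest.raises(ac.InvalidParameter):
            ac.ref_length_bbox(np.zeros((1, 3)))
        with pytest.raises(ac.InvalidParameter):
            ac.ref_length_knn(np.random.default_rng(0).random((10, 3)), 10)


class TestAlphaFromK:
    def test_linear_scaling(self):
        lref = ac.ReferenceLength(3.0, "bbox_diagonal", 10)
        assert ac.alpha_from_k(2.0, lref) == 6.0
        assert ac.alpha_from_k(1.0, lref) == 3.0

    def test_nonpositive_k_rejected(self):
        lref = ac.ReferenceLength(3.0, "bbox_diagonal", 10)
        with pytest.raises(ac.InvalidParameter):
            ac.alpha_from_k(0.0, lref)


class TestGrid:
    def test_two_point_grid_is_endpoints(self):
        g = ac.build_grid(2)
        assert np.allclose(g.values, [0.1, 10_000.0])

    def test_log_midpoint(self):
        g = ac.build_grid(3, 1, 100)
        assert np.allclose(g.values, [1, 10, 100])

    def test_constant_ratio(self):
        g = ac.build_grid()
        assert g.n == 200
        ratios = g.values[1:] / g.values[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)
        assert g.values[0] == pytest.approx(0.1)
        assert g.values[-1] == pytest.approx(10_000.0)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ac.InvalidParameter):
            ac.build_grid(10, 5, 5)
        with pytest.raises(ac.InvalidParameter):
            ac.build_grid(1)


class TestAlphaCurve:
    def test_monotone_and_tops_out_at_hull(self, suite_runs):
        for name, run in suite_runs.items():
            v = run["curve"].volume_mm3
            assert np.all(np.diff(v) >= 0), name
            hull = ac.convex_hull_volume(run["cloud"])
            assert v[-1] == pytest.approx(hull, rel=1e-9)

    def test_percent_column(self, suite_runs):
        run = suite_runs["rod"]
        pct = run["curve"].volume_pct_of_raw
        assert pct[-1] > 100.0  # coarse fits overshoot raw volume

    def test_dumbbell_fragments_as_k_decreases(self):
        vol = ac.make_dumbbell(cluster_gap=14, cluster_radius=4, voxel_size_mm=1)
        pc = ac.downsample(ac.to_point_cloud(vol), 500, seed=0)
        lref = ac.ref_length_knn(pc, 20)
        curve = ac.alpha_curve(pc, lref, ac.build_grid(100), raw_volume_mm3=1.0)
        assert curve.n_components[-1] == 1  # hull level: one body
        assert 2 in curve.n_components  # fragments into the two balls

    def test_breakdown_k_bounded_by_gap_geometry(self):
        gap, r = 14.0, 4.0
        vol = ac.make_dumbbell(cluster_gap=gap, cluster_radius=r, voxel_size_mm=1)
        pc = ac.downsample(ac.to_point_cloud(vol), 500, seed=0)
        lref = ac.ref_length_knn(pc, 20)
        curve = ac.alpha_curve(pc, lref, ac.build_grid(200), raw_volume_mm3=1.0)
        kb = ac.breakdown_k(curve)
        assert kb is not None
        # bridging the empty gap needs a circumsphere spanning at least
        # half the centre distance
        assert ac.alpha_from_k(kb, lref) < gap

    def test_single_tet_never_fragments(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        lref = ac.ref_length_centroid(pts)
        curve = ac.alpha_curve(pts, lref, ac.build_grid(50), raw_volume_mm3=1.0)
        assert ac.breakdown_k(curve) is None


class TestOptimalK:
    def test_converges_on_dimpled_sphere(self, dimpled_sphere_run):
        run = dimpled_sphere_run
        res = ac.optimal_k(run["cloud"], run["l_ref"], run["raw"], tri=run["tri"])
        assert res.converged
        assert res.relative_volume_error < 1e-4

    def test_matches_bisection_oracle(self, dimpled_sphere_run):
        run = dimpled_sphere_run
        res = ac.optimal_k(run["cloud"], run["l_ref"], run["raw"], tri=run["tri"])
        kb = bisect_k_star(run["tri"], run["l_ref"].value_mm, run["raw"])
        assert abs(res.k_star - kb) / kb < 0.01

    def test_scale_invariance_of_cloud(self, dimpled_sphere_run):
        # identical cloud at 2x size, reference length recomputed by knn
        run = dimpled_sphere_run
        res1 = ac.optimal_k(run["cloud"], run["l_ref"], run["raw"], tri=run["tri"])
        big = PointCloud(run["cloud"].coordinates * 2.0)
        lref2 = ac.ref_length_knn(big)
        res2 = ac.optimal_k(big, lref2, run["raw"] * 8.0)
        assert abs(res2.k_star - res1.k_star) / res1.k_star < 0.01

    def test_unattainable_raw_volume_raises(self, dimpled_sphere_run):
        run = dimpled_sphere_run
        hull = ac.convex_hull_volume(run["cloud"])
        with pytest.raises(ac.NoCrossing):
            ac.optimal_k(run["cloud"], run["l_ref"], 2 * hull, tri=run["tri"])


class TestCoarsestContribution:
    def test_interior_point_never_labelled(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(400, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = np.r_[u, [[0.0, 0.0, 0.0]]]  # sphere surface + one deep interior point
        lref = ac.ref_length_centroid(pts)
        labels = ac.coarsest_contribution(pts, lref, ac.build_grid(30, 0.8, 100))
        assert np.isnan(labels[-1])
        assert np.isfinite(labels[:-1]).all()

    def test_hull_vertices_labelled_at_top_k(self, cube_corners):
        lref = ac.ref_length_centroid(cube_corners)
        grid = ac.build_grid(20, 0.5, 100)
        labels = ac.coarsest_contribution(cube_corners, lref, grid)
        assert np.allclose(labels, grid.values.max())

    def test_groove_floor_labelled_finer_than_outer_surface(self, suite_runs):
        run = suite_runs["grooved_rod"]
        spec, cloud = run["spec"], run["cloud"]
        labels = ac.coarsest_contribution(
            cloud, run["l_ref"], ac.build_grid(40, 0.2, 200), tri=run["tri"]
        )
        pts = cloud.coordinates
        r, rc, w, d = spec.radius, spec.arc_radius, spec.groove_width, spec.groove_depth
        rho = np.hypot(pts[:, 0], pts[:, 1])
        u, z = rho - rc, pts[:, 2]  # tube cross-section coordinates
        # groove floor: under the channel, just below the cut depth
        floor = (np.abs(z) < w / 2) & (u > r - d - 2) & (u < r - d)
        # tube surface away from the groove (the convex flanks)
        outer = (u**2 + z**2 > (r - 2) ** 2) & (np.abs(z) > w / 2 + 2)
        lab_floor = labels[floor & np.isfinite(labels)]
        lab_outer = labels[outer & np.isfinite(labels)]
        assert lab_floor.size > 20 and lab_outer.size > 20
        assert np.median(lab_floor) < np.median(lab_outer)
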