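import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import alphacomplexity as ac
from alphacomplexity.alpha import alpha_complex, delaunay_tets

from _oracles import brute_alpha

REGULAR_TET = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0.5, math.sqrt(3) / 2, 0],
        [0.5, math.sqrt(3) / 6, math.sqrt(2 / 3)],
    ]
)
CORNER_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


class TestCircumradius:
    def test_regular_tetrahedron(self):
        assert ac.circumradius(REGULAR_TET) == pytest.approx(math.sqrt(3 / 8), rel=1e-12)

    def test_corner_tetrahedron(self):
        # circumcentre of the unit corner tet is (1/2, 1/2, 1/2)
        assert ac.circumradius(CORNER_TET) == pytest.approx(math.sqrt(3) / 2, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(c=st.floats(0.01, 100), seed=st.integers(0, 10_000))
    def test_similarity_scaling(self, c, seed):
        rng = np.random.default_rng(seed)
        tet = rng.random((4, 3))
        r = ac.circumradius(tet)
        if math.isinf(r):
            return
        assert ac.circumradius(c * tet) == pytest.approx(c * r, rel=1e-6)

    def test_flat_tetrahedron_flagged(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        assert math.isinf(ac.circumradius(flat))


class TestDelaunay:
    def test_four_points_single_tet(self):
        tri = delaunay_tets(CORNER_TET)
        assert tri.n_tets == 1
        assert tri.volumes[0] == pytest.approx(1 / 6)

    def test_cube_volume_sums_to_one(self, cube_corners):
        tri = delaunay_tets(cube_corners)
        assert tri.volumes.sum() == pytest.approx(1.0, rel=1e-12)
        assert tri.volumes.sum() == pytest.approx(
            ac.convex_hull_volume(cube_corners), rel=1e-12
        )

    def test_coplanar_rejected(self):
        with pytest.raises(ac.DegenerateInput):
            delaunay_tets(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]]))
        with pytest.raises(ac.DegenerateInput):
            delaunay_tets(CORNER_TET[:3])


class TestAlphaComplex:
    def test_single_tet_threshold(self):
        tri = delaunay_tets(REGULAR_TET)
        kept = alpha_complex(tri, 0.7)
        assert len(kept.kept) == 1
        assert kept.volume_mm3 == pytest.approx(math.sqrt(2) / 12, rel=1e-9)
        empty = alpha_complex(tri, 0.5)
        assert len(empty.kept) == 0
        assert empty.volume_mm3 == 0.0
        assert empty.n_components == 0
        assert len(empty.boundary) == 0

    def test_tie_is_kept(self):
        tri = delaunay_tets(REGULAR_TET)
        r = tri.circumradii[0]
        assert len(alpha_complex(tri, r).kept) == 1

    def test_infinite_alpha_is_convex_hull(self, rng):
        pts = rng.random((200, 3))
        tri = delaunay_tets(pts)
        shape = alpha_complex(tri, np.inf)
        assert shape.volume_mm3 == pytest.approx(ac.convex_hull_volume(pts), rel=1e-12)
        assert shape.n_components == 1

    def test_shape_volume_consistency(self, rng):
        pts = rng.random((100, 3))
        tri = delaunay_tets(pts)
        shape = alpha_complex(tri, float(np.median(tri.circumradii)))
        assert ac.shape_volume(shape) == pytest.approx(shape.volume_mm3, rel=1e-9)

    def test_monotone_nesting(self, rng):
        pts = rng.random((300, 3))
        tri = delaunay_tets(pts)
        alphas = np.quantile(tri.circumradii[np.isfinite(tri.circumradii)], np.linspace(0, 1, 9))
        prev_kept: set = set()
        prev_vol = 0.0
        for a in alphas:
            shape = alpha_complex(tri, float(a))
            kept = set(shape.kept.tolist())
            assert prev_kept <= kept
            assert shape.volume_mm3 >= prev_vol - 1e-12
            prev_kept, prev_vol = kept, shape.volume_mm3


class TestBoundary:
    def test_single_tet_has_four_faces(self):
        tri = delaunay_tets(CORNER_TET)
        shape = alpha_complex(tri, np.inf)
        assert len(shape.boundary) == 4

    def test_two_tets_sharing_face_have_six(self):
        # apex far enough outside the first circumsphere that the shared
        # face is not flipped away
        pts = np.r_[CORNER_TET, [[2.0, 2.0, 2.0]]]
        tri = delaunay_tets(pts)
        assert tri.n_tets == 2
        shape = alpha_complex(tri, np.inf)
        assert len(shape.boundary) == 6

    def test_outward_orientation(self, rng):
        # signed volume of the boundary surface equals the complex volume
        pts = rng.random((150, 3))
        tri = delaunay_tets(pts)
        shape = alpha_complex(tri, np.inf)
        tris = shape.boundary
        a, b, c = (tri.points[tris[:, i]] for i in range(3))
        signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
        assert signed == pytest.approx(shape.volume_mm3, rel=1e-9)

    def test_closed_surface_for_single_component(self, rng):
        # every boundary edge is shared by exactly two boundary triangles
        pts = rng.random((120, 3))
        tri = delaunay_tets(pts)
        shape = alpha_complex(tri, np.inf)
        edges = {}
        for t in shape.boundary:
            for e in ((t[0], t[1]), (t[1], t[2]), (t[0], t[2])):
                e = (min(e), max(e))
                edges[e] = edges.get(e, 0) + 1
        assert set(edges.values()) == {2}


class TestComponents:
    def test_counts(self, rng):
        two = np.r_[CORNER_TET, CORNER_TET + 10.0]
        tri = delaunay_tets(two)
        # at a fine alpha only the two original tets survive
        fine = alpha_complex(tri, 1.0)
        assert fine.n_components == 2
        assert ac.count_components(fine) == 2
        one = alpha_complex(delaunay_tets(CORNER_TET), np.inf)
        assert one.n_components == 1

    def test_filtration_matches_direct_count(self, rng):
        pts = rng.random((250, 3))
        tri = delaunay_tets(pts)
        for q in (0.05, 0.2, 0.5, 0.9):
            a = float(np.quantile(tri.circumradii[np.isfinite(tri.circumradii)], q))
            shape = alpha_complex(tri, a)
            assert shape.n_components == ac.count_components(shape)


class TestBruteForceOracle:
    @pytest.mark.parametrize("n,seed", [(20, 0), (35, 1), (50, 2)])
    def test_small_clouds_match_naive_recomputation(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 3))
        tri = delaunay_tets(pts)
        finite = tri.circumradii[np.isfinite(tri.circumradii)]
        alphas = np.quantile(finite, np.linspace(0.02, 1.0, 10))
        for a in alphas:
            shape = alpha_complex(tri, float(a))
            vol, boundary, comps = brute_alpha(pts, float(a))
            assert shape.volume_mm3 == pytest.approx(vol, rel=1e-9, abs=1e-12)
            got = {tuple(sorted(t)) for t in shape.boundary.tolist()}
            assert got == boundary
            assert shape.n_components == comps


class TestHullVolume:
    def test_unit_cube(self, cube_corners):
        assert ac.convex_hull_volume(cube_corners) == pytest.approx(1.0, rel=1e-12)

    def test_four_points(self):
        assert ac.convex_hull_volume(CORNER_TET) == pytest.approx(1 / 6, rel=1e-12)

    def test_ball_sample_increases_towards_analytic(self, rng):
        vols = []
        for n in (50, 500, 5000):
            u = rng.normal(size=(n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            r = rng.random(n) ** (1 / 3)
            vols.append(ac.convex_hull_volume(u * r[:, None]))
        assert vols[0] < vols[1] < vols[2] < 4 / 3 * math.pi
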