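"""Delaunay alpha-complex construction over 3D point clouds.

An alpha complex is the subcomplex of the Delaunay tetrahedralization
containing every tetrahedron whose circumscribing sphere has radius at most
alpha.  The alpha *shape* is its boundary.  As alpha grows from 0 to
infinity the complex sweeps from empty, through progressively coarser fits,
to the full triangulation (whose union is the convex hull), and the kept
sets are nested; alpha-shape volume is therefore non-decreasing in alpha.

The alpha criterion here is applied to tetrahedra only, and volume is the
sum of kept tetrahedron volumes.  The full simplicial alpha intervals of
the general theory (singular faces/edges) contribute nothing to volume and
are not tracked.

Tetrahedra flatter than a relative degeneracy tolerance have numerically
meaningless circumcentre solves and vanishing volume.  They are real
simplices nonetheless - voxel-lattice clouds produce exactly coplanar,
concyclic 4-point Delaunay cells - and dropping them would spuriously
disconnect the complex.  Their filtration value is therefore the smallest
enclosing-sphere radius, which is the degenerate limit of the circumradius
(a flat Delaunay cell is concyclic, so the limit is its circumcircle
radius); their volume contribution is zero either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .errors import DegenerateInput
from .preprocess import PointCloud

__all__ = [
    "Tetrahedralization",
    "AlphaShape",
    "delaunay_tets",
    "circumradius",
    "alpha_complex",
    "shape_volume",
    "boundary_faces",
    "count_components",
    "convex_hull_volume",
]

#: tetrahedra with volume below DEGENERACY_TOL * (bbox diagonal)^3 are
#: treated as flat: filtered by smallest-enclosing-sphere radius instead of
#: the (numerically meaningless) circumcentre solve
DEGENERACY_TOL = 1e-12


def _as_coords(pc) -> np.ndarray:
    if isinstance(pc, PointCloud):
        return pc.coordinates
    return np.asarray(pc, dtype=float)


def circumradius(verts: np.ndarray) -> float:
    """Radius of the unique sphere through four points.

    Solved via the circumcentre linear system in coordinates translated to
    the first vertex (numerically stabler than the product-of-edge-lengths
    formula).  Near-flat tetrahedra beyond the degeneracy tolerance have no
    well-defined circumsphere and are flagged by returning ``inf``; inside
    a triangulation they are filtered by their smallest enclosing sphere
    instead (see :func:`delaunay_tets`).
    """
    v = np.asarray(verts, dtype=float)
    a, b, c = v[1] - v[0], v[2] - v[0], v[3] - v[0]
    vol6 = abs(np.dot(a, np.cross(b, c)))
    scale = max(np.linalg.norm(a), np.linalg.norm(b), np.linalg.norm(c))
    if scale == 0 or vol6 / 6 < DEGENERACY_TOL * scale**3:
        return float("inf")
    A = np.stack([a, b, c])
    rhs = 0.5 * np.array([a @ a, b @ b, c @ c])
    x = np.linalg.solve(A, rhs)
    return float(np.linalg.norm(x))


def _triangle_circumcentre(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = float(n @ n)
    if nn == 0.0:
        return None
    centre = a + np.cross((ab @ ab) * ac - (ac @ ac) * ab, n) / (2 * nn)
    return centre


def _enclosing_sphere_radius(verts: np.ndarray) -> float:
    """Smallest sphere enclosing four (typically coplanar) points.

    Checks the standard candidate centres - edge midpoints and triangle
    circumcentres - and returns the smallest radius that covers all four
    points.  Exact for flat tetrahedra, where the four-point circumsphere
    does not exist.
    """
    from itertools import combinations

    v = np.asarray(verts, dtype=float)
    best = np.inf
    slack = 1.0 + 1e-9
    for i, j in combinations(range(4), 2):
        centre = (v[i] + v[j]) / 2
        d = np.linalg.norm(v - centre, axis=1)
        if d.max() <= d[[i, j]].max() * slack:
            best = min(best, float(d.max()))
    for i, j, k in combinations(range(4), 3):
        centre = _triangle_circumcentre(v[i], v[j], v[k])
        if centre is None:
            continue
        d = np.linalg.norm(v - centre, axis=1)
        if d.max() <= d[[i, j, k]].max() * slack:
            best = min(best, float(d.max()))
    if not np.isfinite(best):  # fully collinear cell: fall back to span
        best = float(np.linalg.norm(v.max(0) - v.min(0)) / 2)
    return best


@dataclass
class Tetrahedralization:
    """A Delaunay tetrahedralization with precomputed per-tet geometry."""

    points: np.ndarray
    tetrahedra: np.ndarray  # (m, 4) vertex indices
    circumradii: np.ndarray  # (m,) mm; enclosing-sphere radius for flat tets
    volumes: np.ndarray  # (m,) mm^3
    neighbors: np.ndarray  # (m, 4) facet-adjacent tets, -1 at the hull

    # sorted-by-circumradius prefix structure (lazily built)
    _order: np.ndarray | None = field(default=None, repr=False)
    _sorted_radii: np.ndarray | None = field(default=None, repr=False)
    _cum_volume: np.ndarray | None = field(default=None, repr=False)
    _n_components: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_tets(self) -> int:
        return len(self.tetrahedra)

    # -- incremental filtration ------------------------------------------
    #
    # Because kept sets are nested in alpha, volume and component count
    # along a whole refinement grid reduce to prefix quantities over the
    # tetrahedra sorted by circumradius: volume is a cumulative sum, and
    # the component count comes from one incremental union-find pass over
    # the shared-face adjacency.  Every later query is O(log m).
    #
    # Components are counted as *volumes*: a component made entirely of
    # flat (zero-volume) cells is not a fragment, though flat cells do glue
    # solid cells together.

    def _build_filtration(self) -> None:
        order = np.argsort(self.circumradii, kind="stable")
        rs = self.circumradii[order]
        cum = np.cumsum(self.volumes[order])
        rank = np.empty(self.n_tets, dtype=np.int64)
        rank[order] = np.arange(self.n_tets)
        diag = float(np.linalg.norm(self.points.max(0) - self.points.min(0)))
        solid = self.volumes >= DEGENERACY_TOL * diag**3

        parent = np.arange(self.n_tets)
        has_solid = np.zeros(self.n_tets, dtype=bool)

        def find(i: int) -> int:
            root = i
            while parent[root] != root:
                root = parent[root]
            while parent[i] != root:
                parent[i], i = root, parent[i]
            return root

        ncomp = np.empty(self.n_tets + 1, dtype=np.int64)
        ncomp[0] = 0
        n = 0
        for pos in range(self.n_tets):
            t = order[pos]
            has_solid[t] = solid[t]
            if solid[t]:
                n += 1
            for nb in self.neighbors[t]:
                if nb >= 0 and rank[nb] < pos:
                    ra, rb = find(t), find(nb)
                    if ra != rb:
                        if has_solid[ra] and has_solid[rb]:
                            n -= 1
                        parent[ra] = rb
                        has_solid[rb] |= has_solid[ra]
            ncomp[pos + 1] = n
        self._order = order
        self._sorted_radii = rs
        self._cum_volume = cum
        self._n_components = ncomp

    def _prefix_index(self, alpha_mm: float) -> int:
        """Number of tetrahedra with circumradius <= alpha (ties kept)."""
        if self._sorted_radii is None:
            self._build_filtration()
        if np.isinf(alpha_mm):
            return self.n_tets
        return int(np.searchsorted(self._sorted_radii, alpha_mm, side="right"))

    def kept_at(self, alpha_mm: float) -> np.ndarray:
        idx = self._prefix_index(alpha_mm)
        return np.sort(self._order[:idx])

    def volume_at(self, alpha_mm: float) -> float:
        i = self._prefix_index(alpha_mm)
        return float(self._cum_volume[i - 1]) if i else 0.0

    def components_at(self, alpha_mm: float) -> int:
        return int(self._n_components[self._prefix_index(alpha_mm)])

    @property
    def max_finite_circumradius(self) -> float:
        finite = self.circumradii[np.isfinite(self.circumradii)]
        return float(finite.max()) if finite.size else 0.0


def delaunay_tets(pc) -> Tetrahedralization:
    """Delaunay tetrahedralization with per-tet circumradii, computed once.

    Raises ``DegenerateInput`` for fewer than 4 points or (near-)coplanar
    input.
    """
    pts = _as_coords(pc)
    if pts.shape[0] < 4:
        raise DegenerateInput("need at least 4 points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 3:
        raise DegenerateInput("points are collinear or coplanar")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise DegenerateInput(str(exc)) from exc
    tets = tri.simplices
    v = pts[tets]
    a, b, c = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]
    vols = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
    diag = float(np.linalg.norm(pts.max(0) - pts.min(0)))
    degenerate = vols < DEGENERACY_TOL * diag**3
    radii = np.empty(len(tets))
    for i in np.nonzero(degenerate)[0]:
        radii[i] = _enclosing_sphere_radius(v[i])
    ok = ~degenerate
    if ok.any():
        A = np.stack([a[ok], b[ok], c[ok]], axis=1)
        rhs = 0.5 * np.stack(
            [
                np.einsum("ij,ij->i", a[ok], a[ok]),
                np.einsum("ij,ij->i", b[ok], b[ok]),
                np.einsum("ij,ij->i", c[ok], c[ok]),
            ],
            axis=1,
        )
        x = np.linalg.solve(A, rhs[..., None])[..., 0]
        radii[ok] = np.linalg.norm(x, axis=1)
    return Tetrahedralization(
        points=pts,
        tetrahedra=tets,
        circumradii=radii,
        volumes=vols,
        neighbors=tri.neighbors,
    )


@dataclass
class AlphaShape:
    """One alpha-complex fit: kept tetrahedra and derived quantities."""

    alpha_mm: float
    kept: np.ndarray  # indices into the parent tetrahedralization
    volume_mm3: float
    n_components: int
    tri: Tetrahedralization
    k: float | None = None
    _boundary: np.ndarray | None = field(default=None, repr=False)

    @property
    def boundary(self) -> np.ndarray:
        if self._boundary is None:
            self._boundary = boundary_faces(self)
        return self._boundary


def alpha_complex(tri: Tetrahedralization, alpha_mm: float, k: float | None = None) -> AlphaShape:
    """The alpha complex at one radius: tets with circumradius <= alpha.

    Ties (circumradius exactly equal to alpha) are kept, so that kept sets
    nest exactly along any increasing alpha sequence.  ``alpha = inf``
    keeps everything and coincides with the convex hull.
    """
    kept = tri.kept_at(alpha_mm)
    return AlphaShape(
        alpha_mm=float(alpha_mm),
        kept=kept,
        volume_mm3=tri.volume_at(alpha_mm),
        n_components=tri.components_at(alpha_mm),
        tri=tri,
        k=k,
    )


def shape_volume(shape: AlphaShape) -> float:
    """Sum of kept tetrahedron volumes (mm^3)."""
    return float(shape.tri.volumes[shape.kept].sum())


def _face_array(tets: np.ndarray) -> np.ndarray:
    """All 4 faces of each tet, each face paired with its opposite vertex.

    Returns an (4m, 4) array: columns 0-2 the face (vertex order preserved
    from the tet), column 3 the opposite vertex.
    """
    f = tets[:, [[1, 2, 3, 0], [0, 2, 3, 1], [0, 1, 3, 2], [0, 1, 2, 3]]]
    return f.reshape(-1, 4)


def boundary_faces(shape: AlphaShape) -> np.ndarray:
    """Triangles occurring in exactly one kept tetrahedron, oriented outward.

    Each returned triple ``(a, b, c)`` is wound so that
    ``(b - a) x (c - a)`` points away from the kept tetrahedron it belongs
    to.
    """
    if len(shape.kept) == 0:
        return np.empty((0, 3), dtype=np.int64)
    faces = _face_array(shape.tri.tetrahedra[shape.kept])
    tri_sorted = np.sort(faces[:, :3], axis=1)
    n = shape.tri.points.shape[0]
    key = (tri_sorted[:, 0].astype(np.int64) * n + tri_sorted[:, 1]) * n + tri_sorted[:, 2]
    order = np.argsort(key, kind="stable")
    k = key[order]
    first = np.r_[True, k[1:] != k[:-1]]
    last = np.r_[k[1:] != k[:-1], True]
    single = order[first & last]
    out = faces[single]
    # orient: normal of (a, b, c) must point away from the opposite vertex d
    p = shape.tri.points
    a, b, c, d = (p[out[:, i]] for i in range(4))
    inward = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) > 0
    tris = out[:, :3].copy()
    tris[inward] = tris[inward][:, [0, 2, 1]]
    return tris


def count_components(shape: AlphaShape) -> int:
    """Connected components of kept tetrahedra under shared-face adjacency.

    Counted as *volumes*: components consisting solely of flat
    (zero-volume) cells are not fragments, although flat cells still act
    as connectors between solid ones.
    """
    m = len(shape.kept)
    if m == 0:
        return 0
    tri = shape.tri
    pos = -np.ones(tri.n_tets, dtype=np.int64)
    pos[shape.kept] = np.arange(m)
    nb = tri.neighbors[shape.kept]
    src = np.repeat(np.arange(m), 4)
    dst_global = nb.ravel()
    ok = dst_global >= 0
    src, dst_global = src[ok], dst_global[ok]
    dst = pos[dst_global]
    ok = dst >= 0
    src, dst = src[ok], dst[ok]
    graph = coo_matrix((np.ones(len(src)), (src, dst)), shape=(m, m))
    _, labels = connected_components(graph, directed=False)
    diag = float(np.linalg.norm(tri.points.max(0) - tri.points.min(0)))
    solid = tri.volumes[shape.kept] >= DEGENERACY_TOL * diag**3
    return int(np.unique(labels[solid]).size)


def convex_hull_volume(pc) -> float:
    """Convex-hull volume, computed independently of the alpha machinery.

    Serves both as the alpha = infinity limit and as an oracle for it.
    """
    pts = _as_coords(pc)
    if pts.shape[0] < 4:
        raise DegenerateInput("need at least 4 points")
    try:
        return float(ConvexHull(pts).volume)
    except QhullError as exc:
        raise DegenerateInput(str(exc)) from exc
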