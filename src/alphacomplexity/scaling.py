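"""Reference lengths, the refinement grid, alpha curves and optimal k.

The alpha radius applied to a specimen is scaled by a per-specimen
reference length,

    alpha = k * l_ref,

so that the dimensionless refinement coefficient ``k`` is comparable
between specimens of different absolute size: two identical shapes at 1x
and 2x size (equal point counts) need alpha radii in the same 2:1 ratio to
reach the same refinement of fit, and ``k`` absorbs exactly that ratio.

Three reference-length estimators are provided; the mean distance of each
point to its nearest 100 neighbours is the package default, because it
scales alpha to the inter-point spacing and makes alpha shapes of all
specimens in a study break down (fragment into multiple volumes) at a
consistent refinement coefficient.

The *optimal* refinement coefficient k* is the k at which alpha-shape
volume equals the specimen's raw voxel volume: coarser fits overshoot raw
volume, finer fits undershoot, and the crossing summarises the whole alpha
curve in one number.  Smaller k* means a more complex shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .alpha import Tetrahedralization, convex_hull_volume, delaunay_tets
from .errors import InvalidParameter, NoCrossing
from .preprocess import PointCloud

__all__ = [
    "ReferenceLength",
    "RefinementGrid",
    "AlphaCurve",
    "OptimalResult",
    "ref_length_bbox",
    "ref_length_centroid",
    "ref_length_knn",
    "reference_length",
    "alpha_from_k",
    "build_grid",
    "alpha_curve",
    "optimal_k",
    "breakdown_k",
    "coarsest_contribution",
]


def _coords(pc) -> np.ndarray:
    if isinstance(pc, PointCloud):
        return pc.coordinates
    return np.asarray(pc, dtype=float)


@dataclass(frozen=True)
class ReferenceLength:
    """A scalar summary of point-cloud scale (mm)."""

    value_mm: float
    method: str  # bbox_diagonal | centroid_mean | knn_mean
    n_source_points: int
    k_neighbors: int | None = None

    def __post_init__(self) -> None:
        if not self.value_mm > 0:
            raise InvalidParameter("reference length must be positive")


def ref_length_bbox(pc) -> ReferenceLength:
    """Diagonal of the axis-aligned bounding box."""
    pts = _coords(pc)
    if pts.shape[0] < 2:
        raise InvalidParameter("need at least 2 points")
    diag = float(np.linalg.norm(pts.max(0) - pts.min(0)))
    if diag == 0:
        raise InvalidParameter("degenerate cloud: zero bounding box")
    return ReferenceLength(diag, "bbox_diagonal", pts.shape[0])


def ref_length_centroid(pc) -> ReferenceLength:
    """Mean Euclidean distance of all points from the cloud centroid."""
    pts = _coords(pc)
    if pts.shape[0] < 2:
        raise InvalidParameter("need at least 2 points")
    d = np.linalg.norm(pts - pts.mean(0), axis=1)
    value = float(d.mean())
    if value == 0:
        raise InvalidParameter("degenerate cloud: all points coincide")
    return ReferenceLength(value, "centroid_mean", pts.shape[0])


def ref_length_knn(pc, k_neighbors: int = 100) -> ReferenceLength:
    """Mean over points of the mean distance to their k nearest neighbours.

    Self-distances are excluded.  This is the default scaling of the
    package: it tracks inter-point spacing, so equally refined fits of
    differently sized (or differently dense) clouds share the same k.
    """
    pts = _coords(pc)
    if k_neighbors < 1:
        raise InvalidParameter("k_neighbors must be >= 1")
    if k_neighbors >= pts.shape[0]:
        raise InvalidParameter("k_neighbors must be < number of points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=k_neighbors + 1, workers=-1)
    value = float(d[:, 1:].mean())
    if value == 0:
        raise InvalidParameter("degenerate cloud: duplicate points only")
    return ReferenceLength(value, "knn_mean", pts.shape[0], k_neighbors)


_METHODS = {
    "bbox_diagonal": ref_length_bbox,
    "centroid_mean": ref_length_centroid,
    "knn_mean": ref_length_knn,
}


def reference_length(pc, method: str = "knn_mean", k_neighbors: int = 100) -> ReferenceLength:
    """Dispatch to one of the three reference-length estimators."""
    if method not in _METHODS:
        raise InvalidParameter(f"unknown reference-length method {method!r}")
    if method == "knn_mean":
        return ref_length_knn(pc, k_neighbors)
    return _METHODS[method](pc)


def alpha_from_k(k: float, l_ref: ReferenceLength | float) -> float:
    """alpha = k * l_ref (mm)."""
    if not k > 0:
        raise InvalidParameter("refinement coefficient k must be positive")
    value = l_ref.value_mm if isinstance(l_ref, ReferenceLength) else float(l_ref)
    return k * value


@dataclass(frozen=True)
class RefinementGrid:
    """Log-uniform grid of refinement coefficients, endpoints included."""

    values: np.ndarray
    lo: float
    hi: float

    @property
    def n(self) -> int:
        return len(self.values)


def build_grid(n: int = 200, lo: float = 0.1, hi: float = 10_000.0) -> RefinementGrid:
    """``n`` log-uniformly spaced k values from ``lo`` to ``hi`` inclusive."""
    if not (0 < lo < hi):
        raise InvalidParameter("need 0 < lo < hi")
    if n < 2:
        raise InvalidParameter("need n >= 2")
    return RefinementGrid(np.geomspace(lo, hi, n), lo, hi)


@dataclass
class AlphaCurve:
    """Alpha-shape volume and component count along a refinement grid."""

    specimen_id: str
    l_ref: ReferenceLength
    raw_volume_mm3: float
    k: np.ndarray
    alpha_mm: np.ndarray
    volume_mm3: np.ndarray
    n_components: np.ndarray
    tri: Tetrahedralization = field(repr=False)

    @property
    def volume_pct_of_raw(self) -> np.ndarray:
        return 100.0 * self.volume_mm3 / self.raw_volume_mm3

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "specimen_id": self.specimen_id,
                "k": self.k,
                "alpha_mm": self.alpha_mm,
                "volume_mm3": self.volume_mm3,
                "volume_pct_raw": self.volume_pct_of_raw,
                "n_components": self.n_components,
            }
        )


def alpha_curve(
    pc,
    l_ref: ReferenceLength,
    grid: RefinementGrid | None = None,
    raw_volume_mm3: float | None = None,
    specimen_id: str = "",
    tri: Tetrahedralization | None = None,
) -> AlphaCurve:
    """Sweep the refinement grid and record volume and fragmentation.

    The Delaunay tetrahedralization is computed once and reused for every
    grid value; each evaluation is a binary search into the circumradius
    filtration.
    """
    grid = grid or build_grid()
    if tri is None:
        tri = delaunay_tets(pc)
    alphas = np.array([alpha_from_k(k, l_ref) for k in grid.values])
    vols = np.array([tri.volume_at(a) for a in alphas])
    ncomp = np.array([tri.components_at(a) for a in alphas])
    if raw_volume_mm3 is None:
        raw_volume_mm3 = float("nan")
    return AlphaCurve(
        specimen_id=specimen_id,
        l_ref=l_ref,
        raw_volume_mm3=float(raw_volume_mm3),
        k=np.asarray(grid.values, dtype=float),
        alpha_mm=alphas,
        volume_mm3=vols,
        n_components=ncomp,
        tri=tri,
    )


@dataclass
class OptimalResult:
    """Outcome of the optimal-refinement search."""

    k_star: float
    alpha_mm: float
    volume_at_k_star: float
    raw_volume_mm3: float
    iterations: int
    converged: bool
    tol: float

    @property
    def relative_volume_error(self) -> float:
        return abs(self.volume_at_k_star - self.raw_volume_mm3) / self.raw_volume_mm3


def optimal_k(
    pc,
    l_ref: ReferenceLength,
    raw_volume_mm3: float,
    tol: float = 1e-4,
    grid: RefinementGrid | None = None,
    tri: Tetrahedralization | None = None,
    max_iterations: int = 500,
) -> OptimalResult:
    """Nelder-Mead search for the k at which alpha volume equals raw volume.

    The search variable is log10(k); the simplex is initialised at the
    coarse-grid point whose volume is nearest raw volume, extended one grid
    step towards the coarse side so that, on stepped curves, the largest
    (coarsest) crossing is found.  Convergence requires both stopping
    conditions: the *relative* volume mismatch |V_alpha - V_raw| / V_raw
    below ``tol``, and the simplex spread in log10(k) below ``tol``.  The
    volume condition is interpreted relatively because an absolute mm^3
    threshold would be meaningless across specimen sizes.

    Raises ``NoCrossing`` when raw volume exceeds the convex-hull volume
    (no alpha shape can be coarse enough).  A search that exhausts its
    iteration budget returns with ``converged=False`` rather than raising.
    """
    if not raw_volume_mm3 > 0:
        raise InvalidParameter("raw_volume_mm3 must be positive")
    grid = grid or build_grid()
    if tri is None:
        tri = delaunay_tets(pc)
    hull = convex_hull_volume(tri.points)
    if raw_volume_mm3 > hull:
        raise NoCrossing(
            f"raw volume {raw_volume_mm3:.6g} mm^3 exceeds convex-hull volume "
            f"{hull:.6g} mm^3: the shape is too convex for an optimal "
            "refinement to exist"
        )
    lref = l_ref.value_mm

    def objective(x: np.ndarray) -> float:
        k = 10.0 ** float(x[0])
        return abs(tri.volume_at(k * lref) - raw_volume_mm3) / raw_volume_mm3

    ks = np.asarray(grid.values, dtype=float)
    sweep = np.array([objective(np.array([np.log10(k)])) for k in ks])
    # prefer the larger k on ties: scan from the coarse side
    best = len(ks) - 1 - int(np.argmin(sweep[::-1]))
    x0 = np.log10(ks[best])
    step = np.log10(ks[1] / ks[0])
    res = minimize(
        objective,
        x0=np.array([x0]),
        method="Nelder-Mead",
        options={
            "xatol": tol,
            "fatol": tol,
            "maxiter": max_iterations,
            "initial_simplex": np.array(
                [[x0], [x0 + step if x0 + step <= np.log10(grid.hi) else x0 - step]]
            ),
        },
    )
    k_star = float(np.clip(10.0 ** res.x[0], grid.lo, grid.hi))
    vol = tri.volume_at(k_star * lref)
    rel = abs(vol - raw_volume_mm3) / raw_volume_mm3
    return OptimalResult(
        k_star=k_star,
        alpha_mm=k_star * lref,
        volume_at_k_star=vol,
        raw_volume_mm3=raw_volume_mm3,
        iterations=int(res.nit),
        converged=bool(res.success and rel < tol),
        tol=tol,
    )


def breakdown_k(curve: AlphaCurve) -> float | None:
    """Largest grid k at which the alpha shape is not one connected volume.

    Returns ``None`` if the shape never fragments on the grid.  An empty
    complex (zero components, below the finest surviving refinement) is
    "no shape", not fragmentation.
    """
    broken = curve.n_components > 1
    if not broken.any():
        return None
    return float(curve.k[np.nonzero(broken)[0].max()])


def coarsest_contribution(
    pc,
    l_ref: ReferenceLength,
    grid: RefinementGrid | None = None,
    tri: Tetrahedralization | None = None,
) -> np.ndarray:
    """Per-point label: the coarsest (largest) grid k at which the point
    lies on the alpha-shape boundary.

    A point "contributes" to an alpha shape when it is a vertex of at least
    one boundary face.  Points that are never on a boundary at any grid
    refinement (deep interior points) are labelled ``nan``.  Smaller labels
    mark points inside concave features that only a fine alpha can reach.
    """
    from .alpha import alpha_complex

    grid = grid or build_grid()
    if tri is None:
        tri = delaunay_tets(pc)
    n = tri.points.shape[0]
    labels = np.full(n, np.nan)
    for k in sorted(np.asarray(grid.values, dtype=float), reverse=True):
        shape = alpha_complex(tri, alpha_from_k(k, l_ref), k=k)
        tris = shape.boundary
        if tris.size == 0:
            continue
        verts = np.unique(tris)
        fresh = verts[np.isnan(labels[verts])]
        labels[fresh] = k
    return labels
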