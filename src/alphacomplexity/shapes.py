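"""Voxelised geometric primitives with analytically known volumes.

These fixtures stand in for real scans: every downstream stage of the
pipeline (preprocessing, alpha fitting, optimal-refinement search,
comparator metrics) can be exercised against closed-form ground truth.

Voxel membership is by centre inclusion: a voxel is foreground iff its
centre lies inside the analytic solid, matching binarised-CT semantics.
All generators are fully deterministic (identical spec -> bit-identical
grid); surface dimples are placed on low-discrepancy lattices, not drawn
from an RNG.

A note on convexity: the optimal-refinement method compares alpha-shape
volume against raw voxel volume, and an alpha shape can never exceed the
convex hull of its point cloud.  For a *convex* voxelised solid the hull of
the voxel-centre cloud is a few percent *smaller* than the raw voxel
volume, so the two curves never cross and no optimal refinement exists.
Real bones are never convex at this level (their coarse fits overshoot raw
volume by 25-300%), and the dimpling option below gives the primitives the
same property while keeping the volume bookkeeping exact where a closed
form exists (sphere dimples use the sphere-sphere lens formula).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidShapeSpec, Unsupported
from .preprocess import BinaryVolume

__all__ = [
    "ShapeSpec",
    "make_shape",
    "analytic_volume",
    "make_dumbbell",
    "fixture_suite",
    "dimpled_sphere_spec",
]

KINDS = ("sphere", "capsule", "grooved_capsule", "curved_rod", "hollow_sphere")

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one voxelised primitive (all lengths in mm).

    kind            one of ``sphere | capsule | grooved_capsule |
                    curved_rod | hollow_sphere``
    radius          sphere/tube radius
    length          cylindrical-section length (capsule kinds)
    arc_radius      centreline arc radius (curved_rod); must exceed ``radius``
    arc_angle       arc angle in radians (curved_rod), 0 < angle <= pi
    groove_width    width of the rectangular-section channel cut along the
                    long axis on one side (0 = no groove)
    groove_depth    radial depth of that channel, < radius
    shell_thickness hollow_sphere wall thickness (inner = radius - thickness)
    dimple_n        number of hemispherical surface pits (0 = smooth)
    dimple_radius   radius of the carving balls, centred on the surface
    voxel_size_mm   isotropic voxel pitch
    padding_voxels  empty voxels added around the tight bounding box
    """

    kind: str
    radius: float
    voxel_size_mm: float
    length: float = 0.0
    arc_radius: float = 0.0
    arc_angle: float = 0.0
    groove_width: float = 0.0
    groove_depth: float = 0.0
    shell_thickness: float = 0.0
    dimple_n: int = 0
    dimple_radius: float = 0.0
    padding_voxels: int = 2

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        vox = self.voxel_size_mm
        if self.kind not in KINDS:
            raise InvalidShapeSpec(f"unknown kind {self.kind!r}")
        if not (vox > 0):
            raise InvalidShapeSpec("voxel_size_mm must be positive")
        if self.padding_voxels < 0:
            raise InvalidShapeSpec("padding_voxels must be >= 0")
        if not (self.radius > 0):
            raise InvalidShapeSpec("radius must be positive")
        # every feature meant to be resolvable must span >= 3 voxels
        if 2 * self.radius < 3 * vox:
            raise InvalidShapeSpec("diameter spans fewer than 3 voxels")
        if self.kind in ("capsule", "grooved_capsule"):
            if not (self.length > 0):
                raise InvalidShapeSpec("capsule needs length > 0")
        if self.kind == "curved_rod":
            if not (self.arc_radius > self.radius):
                raise InvalidShapeSpec("curved rod needs arc_radius > radius")
            if not (0 < self.arc_angle <= math.pi):
                raise InvalidShapeSpec("arc_angle must lie in (0, pi]")
        if self.kind == "hollow_sphere":
            t = self.shell_thickness
            if not (0 < t < self.radius):
                raise InvalidShapeSpec("need 0 < shell_thickness < radius")
            if t < 3 * vox:
                raise InvalidShapeSpec("shell thinner than 3 voxels")
        if self.has_groove:
            if self.kind not in ("grooved_capsule", "curved_rod"):
                raise InvalidShapeSpec(f"{self.kind} does not take a groove")
            w, d, r = self.groove_width, self.groove_depth, self.radius
            if not (w > 0 and d > 0):
                raise InvalidShapeSpec("groove needs positive width and depth")
            if d >= r:
                raise InvalidShapeSpec("groove_depth must be < radius")
            if w < 3 * vox or d < 3 * vox:
                raise InvalidShapeSpec("groove spans fewer than 3 voxels")
            if (w / 2) ** 2 > r**2 - (r - d) ** 2:
                raise InvalidShapeSpec("groove wider than its chord at depth")
        if self.kind == "grooved_capsule" and not self.has_groove:
            raise InvalidShapeSpec("grooved_capsule needs a groove")
        if self.dimple_n < 0:
            raise InvalidShapeSpec("dimple_n must be >= 0")
        if self.dimple_n > 0:
            rho = self.dimple_radius
            if not (0 < rho < self.radius):
                raise InvalidShapeSpec("need 0 < dimple_radius < radius")
            if 2 * rho < 3 * vox:
                raise InvalidShapeSpec("dimples span fewer than 3 voxels")
            if self.kind == "hollow_sphere":
                raise InvalidShapeSpec("hollow_sphere does not take dimples")
            if self.kind == "sphere":
                # exact volume bookkeeping requires disjoint carving balls
                c = self._dimple_centers()
                d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
                np.fill_diagonal(d2, np.inf)
                if d2.min() <= (2 * rho) ** 2:
                    raise InvalidShapeSpec(
                        "sphere dimples overlap; reduce dimple_n or dimple_radius"
                    )

    @property
    def has_groove(self) -> bool:
        return self.groove_width > 0 or self.groove_depth > 0

    # -- geometry --------------------------------------------------------

    def _dimple_centers(self) -> np.ndarray:
        """Deterministic dimple-ball centres on the outer surface."""
        n = self.dimple_n
        i = np.arange(n) + 0.5
        if self.kind == "sphere":
            # Fibonacci sphere lattice
            phi = np.arccos(1 - 2 * i / n)
            theta = _GOLDEN_ANGLE * np.arange(n)
            d = np.c_[
                np.sin(phi) * np.cos(theta),
                np.sin(phi) * np.sin(theta),
                np.cos(phi),
            ]
            return self.radius * d
        if self.kind in ("capsule", "grooved_capsule"):
            # golden-angle helix over the cylindrical section
            margin = min(self.dimple_radius, self.length / 2)
            z = np.linspace(-self.length / 2 + margin, self.length / 2 - margin, n)
            theta = _GOLDEN_ANGLE * np.arange(n)
            return np.c_[
                self.radius * np.cos(theta), self.radius * np.sin(theta), z
            ]
        if self.kind == "curved_rod":
            # helix along the arc, in the plane normal to the centreline
            phi = (i / n - 0.5) * self.arc_angle * 0.94
            theta = _GOLDEN_ANGLE * np.arange(n)
            u = self.radius * np.cos(theta)  # radial offset
            z = self.radius * np.sin(theta)
            rho = self.arc_radius + u
            return np.c_[rho * np.cos(phi), rho * np.sin(phi), z]
        raise InvalidShapeSpec(f"{self.kind} does not take dimples")

    def _inside(self, pts: np.ndarray) -> np.ndarray:
        """Membership test for an (n, 3) array of mm coordinates."""
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        r = self.radius
        if self.kind == "sphere":
            mask = (pts**2).sum(1) < r**2
        elif self.kind in ("capsule", "grooved_capsule"):
            h = self.length / 2
            dz = z - np.clip(z, -h, h)
            mask = x**2 + y**2 + dz**2 < r**2
            if self.has_groove:
                cut = (
                    (np.abs(y) < self.groove_width / 2)
                    & (x > r - self.groove_depth)
                    & (np.abs(z) <= h)
                )
                mask &= ~cut
        elif self.kind == "curved_rod":
            half = self.arc_angle / 2
            rc = self.arc_radius
            rho = np.hypot(x, y)
            phi = np.arctan2(y, x)
            on_arc = np.abs(phi) <= half
            d2 = np.empty(len(pts))
            d2[on_arc] = (rho[on_arc] - rc) ** 2 + z[on_arc] ** 2
            ends = ~on_arc
            e = np.array(
                [
                    [rc * math.cos(half), rc * math.sin(half), 0.0],
                    [rc * math.cos(half), -rc * math.sin(half), 0.0],
                ]
            )
            de = ((pts[ends, None, :] - e[None, :, :]) ** 2).sum(-1)
            d2[ends] = de.min(1)
            mask = d2 < r**2
            if self.has_groove:
                cut = (
                    on_arc
                    & (rho > rc + r - self.groove_depth)
                    & (np.abs(z) < self.groove_width / 2)
                )
                mask &= ~cut
        elif self.kind == "hollow_sphere":
            d2 = (pts**2).sum(1)
            r_in = r - self.shell_thickness
            mask = (d2 < r**2) & (d2 >= r_in**2)
        else:  # pragma: no cover - guarded by validate()
            raise InvalidShapeSpec(self.kind)
        if self.dimple_n > 0:
            for c in self._dimple_centers():
                mask &= ((pts - c) ** 2).sum(1) >= self.dimple_radius**2
        return mask

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Tight (lo, hi) bounding box of the solid, in mm, axes (x, y, z)."""
        r = self.radius
        if self.kind in ("sphere", "hollow_sphere"):
            lo = np.array([-r, -r, -r])
            hi = -lo
        elif self.kind in ("capsule", "grooved_capsule"):
            h = self.length / 2 + r
            lo = np.array([-r, -r, -h])
            hi = np.array([r, r, h])
        else:  # curved_rod
            half = self.arc_angle / 2
            rc = self.arc_radius
            lo = np.array([rc * math.cos(half) - r, -(rc * math.sin(half) + r), -r])
            hi = np.array([rc + r, rc * math.sin(half) + r, r])
        return lo, hi


def _voxelise(inside, lo, hi, voxel: float, pad: int) -> BinaryVolume:
    """Evaluate a membership function on a voxel-centre lattice."""
    i0 = np.floor(lo / voxel).astype(int) - pad
    i1 = np.ceil(hi / voxel).astype(int) + pad
    nx, ny, nz = (i1 - i0).astype(int)
    xs = (np.arange(i0[0], i1[0]) + 0.5) * voxel
    ys = (np.arange(i0[1], i1[1]) + 0.5) * voxel
    zs = (np.arange(i0[2], i1[2]) + 0.5) * voxel
    # grid is (slice, row, col) = (z, y, x)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.c_[X.ravel(), Y.ravel(), Z.ravel()]
    mask = inside(pts).reshape(nz, ny, nx)
    origin = i0 * voxel
    return BinaryVolume(mask, voxel, origin_mm=origin)


def make_shape(spec: ShapeSpec) -> BinaryVolume:
    """Voxelise a primitive; foreground = voxel centres inside the solid."""
    spec.validate()
    lo, hi = spec._bounds()
    return _voxelise(spec._inside, lo, hi, spec.voxel_size_mm, spec.padding_voxels)


def _groove_section(r: float, w: float, d: float) -> tuple[float, float]:
    """Area and first moment (about the section centre) of the groove cut.

    The cut region in the circular cross-section (local coordinates u along
    the groove's depth axis, v across it) is {u > r - d, |v| < w/2} clipped
    to the disc of radius ``r``.  Requires the groove to be narrower than
    the chord at its depth (validated by ShapeSpec), so the closed forms

        A  = (w/2) sqrt(r^2 - w^2/4) + r^2 asin(w / 2r) - w (r - d)
        Iu = [ (r^2 - (r-d)^2) w - w^3/12 ] / 2

    are exact.
    """
    a = (w / 2) * math.sqrt(r**2 - w**2 / 4) + r**2 * math.asin(w / (2 * r)) - w * (r - d)
    iu = ((r**2 - (r - d) ** 2) * w - w**3 / 12) / 2
    return a, iu


def _lens_volume(big_r: float, small_r: float, dist: float) -> float:
    """Volume of the intersection of two spheres with centre distance ``dist``."""
    return (
        math.pi
        * (big_r + small_r - dist) ** 2
        * (
            dist**2
            + 2 * dist * small_r
            - 3 * small_r**2
            + 2 * dist * big_r
            + 6 * small_r * big_r
            - 3 * big_r**2
        )
        / (12 * dist)
    )


def analytic_volume(spec: ShapeSpec) -> float:
    """Closed-form volume of the solid, in mm^3.

    Supported exactly: sphere (dimpled or smooth; dimple pits are
    sphere-sphere lens volumes), capsule, grooved capsule, curved rod (with
    or without groove; Pappus' theorem: swept cross-section area times the
    centroid path length), hollow sphere.  Dimpled non-spherical kinds have
    no closed form and raise ``Unsupported``.
    """
    spec.validate()
    r = spec.radius
    if spec.kind == "sphere":
        v = 4 / 3 * math.pi * r**3
        if spec.dimple_n:
            v -= spec.dimple_n * _lens_volume(r, spec.dimple_radius, r)
        return v
    if spec.dimple_n:
        raise Unsupported(f"no closed form for a dimpled {spec.kind}")
    if spec.kind in ("capsule", "grooved_capsule"):
        v = math.pi * r**2 * spec.length + 4 / 3 * math.pi * r**3
        if spec.has_groove:
            a, _ = _groove_section(r, spec.groove_width, spec.groove_depth)
            v -= a * spec.length
        return v
    if spec.kind == "curved_rod":
        # Pappus: tube = pi r^2 * (arc length of centroid path); the two
        # hemispherical end caps together add one full ball.
        v = math.pi * r**2 * spec.arc_radius * spec.arc_angle + 4 / 3 * math.pi * r**3
        if spec.has_groove:
            a, iu = _groove_section(r, spec.groove_width, spec.groove_depth)
            v -= spec.arc_angle * (spec.arc_radius * a + iu)
        return v
    if spec.kind == "hollow_sphere":
        r_in = r - spec.shell_thickness
        return 4 / 3 * math.pi * (r**3 - r_in**3)
    raise Unsupported(spec.kind)  # pragma: no cover


def make_dumbbell(
    cluster_gap: float,
    cluster_radius: float,
    voxel_size_mm: float,
    padding_voxels: int = 2,
) -> BinaryVolume:
    """Two disjoint voxelised balls with centres ``cluster_gap`` apart.

    A fixture for component counting and breakdown behaviour: the alpha
    shape over its cloud fragments into two pieces once alpha drops below
    the scale bridging the gap.
    """
    if not (cluster_gap > 2 * cluster_radius):
        raise InvalidShapeSpec("clusters overlap: need gap > 2 * radius")
    if not (cluster_radius > 0 and voxel_size_mm > 0):
        raise InvalidShapeSpec("radius and voxel size must be positive")
    if 2 * cluster_radius < 3 * voxel_size_mm:
        raise InvalidShapeSpec("cluster diameter spans fewer than 3 voxels")
    half = cluster_gap / 2
    centers = np.array([[-half, 0, 0], [half, 0, 0]])

    def inside(pts: np.ndarray) -> np.ndarray:
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        return (d2 < cluster_radius**2).any(1)

    lo = np.array([-half - cluster_radius, -cluster_radius, -cluster_radius])
    hi = -lo
    return _voxelise(inside, lo, hi, voxel_size_mm, padding_voxels)


# -- standard study fixtures ----------------------------------------------


def dimpled_sphere_spec(radius_vox: float = 16.0, voxel_size_mm: float = 1.0) -> ShapeSpec:
    """A sphere with exact-volume surface pits; the simplest valid specimen.

    Pit count and size are fixed so that the pits remove roughly 6% of the
    volume: enough non-convexity for the convex hull of the voxel-centre
    cloud to exceed raw voxel volume (the method's validity precondition)
    while the closed-form volume stays exact.
    """
    r = radius_vox * voxel_size_mm
    return ShapeSpec(
        kind="sphere",
        radius=r,
        voxel_size_mm=voxel_size_mm,
        dimple_n=40,
        dimple_radius=0.2375 * r,
    )


def fixture_suite(voxel_size_mm: float = 1.0, scale: float = 1.0) -> dict[str, ShapeSpec]:
    """Three rod fixtures of increasing shape complexity.

    All three share tube radius, centreline length and the same light
    surface pitting (the mild rugosity every real bone has - and the
    reason a real 'simple' bone still overshoots its raw volume at coarse
    alpha); they differ only in gross features, mirroring the plain /
    grooved / curved-and-grooved progression of ursid, canid and mustelid
    bacula:

    - ``rod``: a gently bowed, pitted rod (simple; its only coarse-scale
      concavity is the slight bow, so its optimal refinement is coarse)
    - ``grooved_rod``: the same rod with a broad longitudinal groove cut
      along the convex side (optimal refinement at the groove scale)
    - ``curved_grooved_rod``: the grooved tube swept along a much tighter
      arc (strong curvature pushes the optimum finer still)

    ``scale`` multiplies every length *including the voxel pitch*, which
    emulates scanning a proportionally larger specimen at proportionally
    coarser resolution; the optimal refinement coefficient is invariant
    under it.
    """
    s = scale
    r = 14.0 * s
    common = dict(voxel_size_mm=voxel_size_mm * s, dimple_n=60, dimple_radius=2.2 * s)
    groove = dict(groove_width=12.0 * s, groove_depth=9.0 * s)
    gentle = dict(arc_radius=120.0 * s, arc_angle=70.0 / 120.0)
    tight = dict(arc_radius=40.0 * s, arc_angle=70.0 / 40.0)
    return {
        "rod": ShapeSpec(kind="curved_rod", radius=r, **gentle, **common),
        "grooved_rod": ShapeSpec(kind="curved_rod", radius=r, **gentle, **groove, **common),
        "curved_grooved_rod": ShapeSpec(kind="curved_rod", radius=r, **tight, **groove, **common),
    }


def rugose_rod_spec(voxel_size_mm: float = 1.0) -> ShapeSpec:
    """A large, densely pitted rod for point-cloud-density sweeps.

    Its surface texture (150 small pits) sits between the sampling scales
    of a 10^4- and a 10^5-point cloud, so the optimal refinement drops
    markedly as density rises - the coastline effect the sweep measures.
    """
    return ShapeSpec(
        kind="curved_rod",
        radius=20.0,
        arc_radius=150.0,
        arc_angle=110.0 / 150.0,
        voxel_size_mm=voxel_size_mm,
        dimple_n=150,
        dimple_radius=2.5,
    )
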