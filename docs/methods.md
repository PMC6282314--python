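# Methods

## The alpha-complex model

The package fits the *simplified* tetrahedral alpha complex: from the
Delaunay tetrahedralization of the point cloud, keep every tetrahedron
whose circumsphere radius is ≤ α (ties kept, so kept sets nest exactly as
α grows). Volume is the sum of kept tetrahedron volumes; the alpha shape
is the set of triangles belonging to exactly one kept tetrahedron,
oriented outward. The general theory's singular faces and edges carry no
volume and are not tracked — volume, components and boundary are the only
quantities the method consumes.

Circumradii are computed once per cloud by solving the circumcentre linear
system in coordinates translated to the first vertex, which is markedly
more stable than the product-of-edge-lengths formula. Tetrahedra flatter
than `1e-12 × (bbox diagonal)³` have no well-defined circumsphere;
voxel-lattice clouds produce them in quantity (exactly coplanar, concyclic
lattice 4-tuples). They are kept in the complex with their *smallest
enclosing sphere* radius as filtration value — for a concyclic flat cell
this is the circumcircle radius, i.e. the exact degenerate limit of the
circumradius — because dropping them disconnects the complex spuriously
while their volume contribution is zero either way. Component counting
likewise counts *volumes*: a connected component consisting solely of flat
cells is not a fragment, though flat cells do glue solid cells together.

Because kept sets are nested, a whole refinement sweep reduces to prefix
quantities over the tetrahedra sorted by filtration radius: volume is a
cumulative sum, the component count comes from one incremental union-find
pass, and every later query (each optimiser evaluation in particular) is a
binary search. The Delaunay triangulation is never recomputed.

## Scaling and the optimal refinement

Alpha radii are scaled per specimen, α = k·l_ref. Three reference lengths
are available — bounding-box diagonal, mean distance to the centroid, and
the default *knn_mean* (mean distance of each point to its 100 nearest
neighbours, self excluded). knn_mean is preferred because it tracks
inter-point spacing: alpha shapes of all specimens in a study then break
down (fragment) at a consistent k (≈ 0.6 on the fixtures here), evidence
that the radii are well scaled to cloud size.

The refinement grid is 200 log-uniform k values over [0.1, 10,000]. The
optimal k\* minimises |V_α − V_raw| by Nelder–Mead in log₁₀ k, seeded at
the best coarse-grid point with the second simplex vertex one grid step
towards the coarse side, so that on stepped curves the coarsest crossing
is found. Convergence requires both |V_α − V_raw|/V_raw < 1e-4 and a
simplex spread in log₁₀ k below 1e-4. The volume tolerance is interpreted
*relatively*: an absolute mm³ reading would be unattainable for small
specimens and vacuous for large ones. V(k) is a step function (each
tetrahedron enters at its filtration radius), so the achievable mismatch
at the crossing is bounded by the local step height; at 10⁴ points the
near-crossing steps are ~10⁻⁵ relative and the tolerance is met, at a few
thousand points it may not be, and the result is then returned flagged
`converged=False` rather than rounded. If raw volume exceeds the
convex-hull volume no crossing exists and `NoCrossing` is raised. The
search is clamped to the grid bounds.

`coarsest_contribution` labels each point with the largest grid k at which
it is a vertex of at least one boundary face ("contributes" to that alpha
shape); points never on a boundary are interior. Points inside concave
features receive systematically finer labels, which localises complexity
on the specimen.

## Validity precondition: hull volume > raw volume

An alpha shape can never exceed the convex hull of its cloud. For every
real bone the hull overshoots raw volume substantially (25–300% on the
curves this method was developed for), so the crossing exists. A perfectly
convex voxelised solid violates the precondition: the hull of voxel-centre
points *inscribes* the solid and falls a few percent short of the voxel
volume (measured here: 7.5% short for a sphere of radius 10 voxels, 2.7%
at radius 20). This is a property of the method, not an implementation
choice — optimal refinement is undefined for convex solids.

## Synthetic fixtures

All testing runs on voxelised primitives with closed-form volumes
(membership by centre inclusion, deterministic bit-identical generation):
sphere, capsule, grooved capsule (rectangular-section channel; segment
area in closed form), curved rod (tube swept along a circular arc; volume
by Pappus' theorem, groove included), hollow sphere, and a two-ball
dumbbell for fragmentation tests. Features are required to span ≥ 3
voxels, the smallest scale the cloud can represent.

Because of the convexity precondition, fixtures used for optimal-
refinement work carry mild surface *pitting*: hemispherical dimples carved
by balls centred on the surface, placed on deterministic low-discrepancy
lattices. On the sphere the pit volumes are exact (sphere–sphere lens
formula; non-overlap is validated), so raw volume can still be checked
against a closed form to voxelisation accuracy (~0.4% at radius 16
voxels). This mirrors real data: actual "simple" bones are rugose and
gently bowed, never convex. The three-rod study suite makes the same
point deliberately — a gently bowed pitted rod (only coarse-scale
concavity → k\* ≈ 29), the same rod with a broad groove (k\* ≈ 1.7), and
the grooved tube on a much tighter arc (k\* ≈ 1.6) — reproducing the
simple < grooved < curved-and-grooved complexity ordering direction seen
across real taxa. What these fixtures do *not* emulate: anisotropic
trabecular interiors, scanner noise and beam hardening, or anatomical
detail beyond gross groove/curvature/rugosity; passing tests demonstrate
the machinery, not segmentation robustness on noisy scans.

## Preprocessing

The stage order is fixed: binarise → close → fill → raw volume → point
cloud → downsample. Binarisation is Otsu's threshold on the full-stack
histogram (already-binary input passes through). Closing uses a 2D disc
per slice (default radius 6 px, the smallest that reliably closes a
periosteal contour), with explicit background padding so the image border
never acts as foreground. Hole filling is slice-wise 2D by default,
mirroring slice-based workflows; a 3D mode is exposed because a
through-going canal is not a 2D hole in every slice — and conversely the
slice-wise fill closes *surface pits* whose cross-section is enclosed
within a slice, an inherent artifact of the 2D protocol worth knowing
about (the pitted test fixtures use the 3D mode for exactly this reason).
Raw volume is always taken from the filled grid *before* downsampling.
Voxels are assumed isotropic; anisotropic input is an error, never
silently resampled. Clouds are downsampled uniformly without replacement
(default 100,000 points) under an explicit seed recorded in every report.

## Comparator metrics

The dissection index needs a watertight mesh at a fixed face budget so
specimens are compared at equal mesh resolution: marching cubes at the 0.5
level of the zero-padded grid, then in-package quadric-error edge-collapse
decimation to 10,000 faces (±1%), with link-condition and normal-flip
guards so the mesh stays a closed manifold; meshes born coarser than the
budget are subdivided first. DI = √SA ∕ ∛V is dimensionless and
scale-invariant; the sphere minimises it at √(4π)/(4π/3)^⅓ ≈ 2.1992, and
an exact cube gives √6 ≈ 2.4495.

Box counting pads the grid to the next power of two and anchors boxes at
the array origin — grid placement is a known arbitrary choice of the
method, so it is fixed and documented rather than optimised. The FD is
the least-squares slope of log N(s) on log(1/s) over a configurable fit
range, defaulting to s = 1 … half the padded extent. Local slopes between
successive octaves are always reported, and a plateau (3 consecutive local
slopes spanning < 0.05) is the diagnostic for genuine fractal scaling.
Solid bodies show a downward boundary bias at coarse s (occupied boundary
boxes outnumber V/s³), so the solid-body limit FD → 3 is only reached on
the fine-scale fit of a large object (radius ≥ 64 voxels, s ≤ 4 here);
thin shells sit near 2 on mid-range fits.

## Pipeline, determinism, problem sizes

`process_specimen` chains the stages and writes a JSON report, the alpha
curve as CSV, the resolved configuration, and optionally boundary meshes
at the hull / intermediate / optimal / broken-down refinements. Batch
runs isolate failures per specimen. The density sweep shuffles the full
cloud once (seeded) and nests each size inside the next, with l_ref fixed
from the smallest cloud so every density sees the same alpha radii; k\*
falls with density (coastline effect) and comparative studies must
therefore fix one cloud size. Identical configuration and seed give
byte-identical CSV output.

Default study conditions are 100,000-point clouds, knn reference length
with 100 neighbours, the 200-point grid, 1e-4 tolerance, closing radius 6
and 10,000-face meshes. The test suite and the acceptance script run the
same machinery at 10⁴-point clouds (10⁵ for the sweep's dense arm), the
size at which the crossing granularity comfortably meets the volume
tolerance while a full study fits in minutes on one CPU.

## Known limitations

- Optimal refinement is undefined for (near-)convex solids (`NoCrossing`).
- k\* depends on cloud density by design; only values at matched density
  are comparable.
- The tetrahedra-only alpha criterion reproduces alpha-shape *volume*
  exactly but not the full boundary topology of the general theory;
  exported meshes can include zero-volume sliver triangles from flat
  cells.
- The decimated isosurface hits the face budget but is not guaranteed
  optimal in the quadric-error sense; DI values depend mildly on the
  budget, which is why it is fixed.
- No scanner-artifact correction (beam hardening, rings) and no
  anisotropic resampling.
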