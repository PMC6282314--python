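"""Generate the synthetic voxelised fixtures and check their volumes.

Every fixture has a closed-form volume, so the voxel count times the voxel
volume can be compared against exact ground truth - the same check that
backs every downstream stage of the pipeline.
"""

import alphacomplexity as ac

print("fixture            voxels   raw (mm^3)   analytic (mm^3)  rel err")
specs = {"dimpled_sphere": ac.dimpled_sphere_spec()}

for name, spec in specs.items():
    vol = ac.make_shape(spec)
    raw = ac.raw_volume(vol)
    analytic = ac.analytic_volume(spec)
    print(
        f"{name:18s} {vol.n_foreground:7d}   {raw:10.1f}   {analytic:13.1f}"
        f"   {abs(raw - analytic) / analytic:.2%}"
    )

# the three-rod study suite has closed forms only for its smooth bases,
# so report voxel counts and the groove/curvature effect on raw volume
suite = ac.fixture_suite()
print()
for name, spec in suite.items():
    vol = ac.make_shape(spec)
    print(f"{name:22s} {vol.n_foreground:7d} voxels, raw {ac.raw_volume(vol):9.1f} mm^3")

print(
    "\nThe grooved and curved variants remove volume from the same rod;"
    "\ntheir increasing concavity is what the optimal refinement measures."
)
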