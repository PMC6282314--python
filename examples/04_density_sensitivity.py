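"""How the optimal refinement depends on point-cloud density.

Denser clouds resolve finer surface texture, so the alpha shape must be
refined further before its volume matches raw volume: k* falls as density
rises (the coastline effect).  The reference length is pinned to the
sparsest cloud so that a given k maps to the same alpha radius at every
density, and the sweep isolates the density effect alone.
"""

import alphacomplexity as ac
from alphacomplexity.pipeline import RunConfig, sensitivity_sweep

spec = ac.shapes.rugose_rod_spec()
vol = ac.make_shape(spec)
specimen = ac.Specimen("rugose_rod", vol, ac.raw_volume(vol), ac.to_point_cloud(vol))
print(f"rugose rod: {vol.n_foreground} voxels available")

table = sensitivity_sweep(specimen, RunConfig(seed=7), sizes=(10_000, 30_000, 100_000))
print(table.to_string(index=False))

print(
    "\nk* decreases with cloud size: sparse clouds smooth the surface"
    "\n(outer contour points are lost) and a coarser fit already matches"
    "\nraw volume.  Comparative studies must therefore fix one cloud size."
)
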