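"""A miniature comparative study: three rods of increasing complexity.

Reproduces the logic of a multi-specimen comparison table: optimal
refinement coefficient (alpha shapes), dissection index (mesh-based) and
box-counting fractal dimension, side by side.  Alpha shapes should order
the fixtures by their concave features; DI rises with surface relief; FD
shows no plateau (these solids are not fractal).
"""

import alphacomplexity as ac

print(f"{'fixture':22s} {'k*':>8s} {'DI':>7s} {'FD':>6s}  plateau")
for name, spec in ac.fixture_suite().items():
    vol = ac.make_shape(spec)
    raw = ac.raw_volume(vol)
    cloud = ac.downsample(ac.to_point_cloud(vol), 10_000, seed=1)
    res = ac.optimal_k(cloud, ac.ref_length_knn(cloud), raw)
    mesh = ac.mesh_surface(vol, 10_000)
    di = ac.dissection_index(mesh)
    fd = ac.fractal_dimension(ac.box_count(vol))
    print(f"{name:22s} {res.k_star:8.3f} {di:7.3f} {fd.fd_slope:6.3f}  {fd.plateau_detected}")

print(
    "\nSmaller k* = finer refinement needed = more complex shape."
    "\nThe groove and then the tight curvature push k* down, while DI rises;"
    "\nFD barely separates the fixtures and detects no fractal plateau."
)
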