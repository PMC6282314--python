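import numpy as np
import pytest

import alphacomplexity as ac


@pytest.fixture(scope="session")
def suite_specs():
    return ac.shapes.fixture_suite()


@pytest.fixture(scope="session")
def suite_runs(suite_specs):
    """Full optimal-refinement runs of the three study fixtures.

    Computed once per session (Delaunay of a 10^4-point cloud per fixture)
    and shared by the ordering, optimiser-consistency and curve tests.
    """
    out = {}
    for name, spec in suite_specs.items():
        vol = ac.make_shape(spec)
        raw = ac.raw_volume(vol)
        cloud = ac.downsample(ac.to_point_cloud(vol), 10_000, seed=3)
        l_ref = ac.ref_length_knn(cloud)
        tri = ac.delaunay_tets(cloud)
        result = ac.optimal_k(cloud, l_ref, raw, tri=tri)
        curve = ac.alpha_curve(cloud, l_ref, ac.build_grid(), raw, name, tri=tri)
        out[name] = {
            "spec": spec,
            "raw": raw,
            "cloud": cloud,
            "l_ref": l_ref,
            "tri": tri,
            "result": result,
            "curve": curve,
        }
    return out


@pytest.fixture(scope="session")
def dimpled_sphere_run():
    """Preprocessed dimpled sphere: the smallest valid end-to-end specimen."""
    spec = ac.dimpled_sphere_spec()
    vol = ac.make_shape(spec)
    raw = ac.raw_volume(vol)
    cloud = ac.downsample(ac.to_point_cloud(vol), 10_000, seed=5)
    l_ref = ac.ref_length_knn(cloud)
    tri = ac.delaunay_tets(cloud)
    return {
        "spec": spec,
        "vol": vol,
        "raw": raw,
        "cloud": cloud,
        "l_ref": l_ref,
        "tri": tri,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def cube_corners():
    return np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
        dtype=float,
    )
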