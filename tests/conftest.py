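"""Shared fixtures: hand-built meshes, phantoms, and the seeded cohort run.

The cohort fixture runs the full filtering pipeline on 20 noisy phantoms and
is session-scoped because several smoothness/fidelity/determinism tests
share it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import shapefilt as sf

COHORT_SEED = 20260919
COHORT_N = 20


def octahedron_mesh(scale: float = 1.0, offset=(0.0, 0.0, 0.0)) -> sf.TriMesh:
    """Regular octahedron with unit 'radius', outward orientation."""
    v = scale * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    ) + np.asarray(offset, dtype=float)
    f = np.array(
        [
            [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
            [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5],
        ]
    )
    return sf.TriMesh(v, f)


def bumpy_ellipsoid_mesh(subdivisions: int = 2) -> sf.TriMesh:
    """Asymmetric closed test surface: scaled icosphere with two off-axis
    bumps, so rigid recovery has a unique solution (no shape symmetries)."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=10.0)
    v = np.asarray(ico.vertices) * np.array([1.3, 1.0, 0.7])
    for p0, amp in ((np.array([8.0, 5.0, 2.0]), 3.0), (np.array([-4.0, -7.0, 3.0]), -2.0)):
        d2 = np.sum((v - p0) ** 2, axis=1)
        v = v + amp * np.exp(-d2 / (2 * 4.0**2))[:, None] * (
            v / np.linalg.norm(v, axis=1, keepdims=True)
        )
    return sf.TriMesh(v, np.asarray(ico.faces))


@pytest.fixture
def octahedron() -> sf.TriMesh:
    return octahedron_mesh()


@pytest.fixture(scope="session")
def ellipsoid_mask() -> sf.LabelVolume:
    """Noise-free ellipsoid phantom, radii (12, 8, 6) mm on a 1 mm grid."""
    return sf.make_phantom(sf.PhantomSpec(shape="ellipsoid", grid_shape=(48, 48, 48)))


@pytest.fixture(scope="session")
def ellipsoid_template(ellipsoid_mask) -> sf.TriMesh:
    return sf.delaunay_template_mesh(
        ellipsoid_mask, sf.ExtractionConfig(keep_largest_component=False)
    )


def build_cohort(seed: int, n: int):
    """Noisy phantom cohort + template + pipeline config (shared conditions).

    A population of smoothly varying ellipsoids, each corrupted with the
    moderate noise model (5% boundary flips, 3 interior holes, 2 spurious
    components).
    """
    base = sf.PhantomSpec(shape="ellipsoid", grid_shape=(48, 48, 48), seed=seed)
    truths = sf.sample_population(base, n=n, variation=0.1, seed=seed)
    noisy = [
        sf.corrupt_mask(t, sf.NoiseSpec(seed=seed * 1000 + i))
        for i, t in enumerate(truths)
    ]
    template = sf.delaunay_template_mesh(
        sf.make_phantom(base), sf.ExtractionConfig(keep_largest_component=False)
    )
    cfg = sf.PipelineConfig(optimizer=sf.OptimSettings(max_iter=60), seed=seed)
    return truths, noisy, template, cfg


@pytest.fixture(scope="session")
def sphere_to_ellipsoid():
    """Shared sphere(r=10) -> ellipsoid(12, 10, 8) LDDMM matching run."""
    import trimesh

    sp = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    template = sf.TriMesh(np.asarray(sp.vertices), np.asarray(sp.faces))
    emask = sf.make_phantom(
        sf.PhantomSpec(
            shape="ellipsoid",
            size_params={"radii_mm": (12.0, 10.0, 8.0)},
            grid_shape=(48, 48, 48),
        )
    )
    target = sf.marching_cubes_extract(emask)
    k = sf.KernelParams(sigma_V=5.0, sigma_W=3.0, gamma=0.1)
    path, deformed, trace = sf.lddmm_match(
        template, target, k, timesteps=10, opt=sf.OptimSettings(max_iter=120)
    )
    d0 = sf.current_distance2(sf.to_current(template), sf.to_current(target), 3.0)
    d_final = sf.lddmm_energy(path, template, sf.to_current(target))[2]
    filt = sf.voxelize_mesh(deformed, emask)
    return {
        "template": template,
        "deformed": deformed,
        "trace": trace,
        "data_reduction": 1.0 - d_final / d0,
        "dsc": sf.dsc(filt, emask),
        "path": path,
    }


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Full pipeline over the 20-phantom cohort (single shared run)."""
    truths, noisy, template, cfg = build_cohort(COHORT_SEED, COHORT_N)
    csv_path = tmp_path_factory.mktemp("cohort") / "cohort.csv"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, table, failures = sf.run_batch(noisy, template, cfg, out_csv=csv_path)
    return {
        "truths": truths,
        "noisy": noisy,
        "template": template,
        "cfg": cfg,
        "results": results,
        "table": table,
        "failures": failures,
        "csv_bytes": csv_path.read_bytes(),
    }
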