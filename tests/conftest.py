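"""Shared fixtures: small analytic meshes and a compact synthetic cohort."""

import numpy as np
import pytest
import trimesh

from kneeshape.mesh import LandmarkSurface, SurfaceMeta
from kneeshape.shape_model import (ShapePopulation, build_shape_model,
                                   procrustes_align)
from kneeshape.synthetic import (SyntheticConfig, make_template_knee,
                                 render_modality, sample_population)


def make_plane(z=0.0, extent=10.0, n=11, topology="plane", flip=False):
    """Square grid patch at height z, wound CCW seen from +z."""
    xs = np.linspace(-extent, extent, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
    i, j = np.meshgrid(np.arange(n - 1), np.arange(n - 1), indexing="ij")
    v00 = (i * n + j).ravel()
    v10 = ((i + 1) * n + j).ravel()
    v01 = (i * n + j + 1).ravel()
    v11 = ((i + 1) * n + j + 1).ravel()
    faces = np.concatenate([np.column_stack([v00, v10, v11]),
                            np.column_stack([v00, v11, v01])])
    if flip:
        faces = faces[:, ::-1]
    return LandmarkSurface(pts, faces, topology)


def make_bumpy_blob(seed=0, n_sub=1, radius=10.0):
    """Non-symmetric closed mesh: icosphere with smooth random bumps."""
    sph = trimesh.creation.icosphere(subdivisions=n_sub, radius=radius)
    pts = np.asarray(sph.vertices, dtype=float)
    rng = np.random.default_rng(seed)
    w = np.zeros(len(pts))
    for _ in range(6):
        c = rng.normal(size=3)
        c /= np.linalg.norm(c)
        w += rng.uniform(-1, 1) * np.exp(-np.sum((pts / radius - c) ** 2, axis=1))
    pts = pts * (1.0 + 0.25 * w[:, None])
    return LandmarkSurface(pts, np.asarray(sph.faces), f"blob{seed}")


@pytest.fixture(scope="session")
def icosphere():
    sph = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return LandmarkSurface(np.asarray(sph.vertices), np.asarray(sph.faces),
                           "icosphere4")


@pytest.fixture(scope="session")
def template():
    return make_template_knee(2)


@pytest.fixture(scope="session")
def small_cohort(template):
    """Quiet 10-knee cohort with paired renders (shared, read-only)."""
    cfg = SyntheticConfig(n_subjects=10, seed=11)
    _, knees = sample_population(cfg, template)
    renders = {k.subject: {m: render_modality(k, m, cfg) for m in ("CT", "MR")}
               for k in knees}
    return cfg, knees, renders


@pytest.fixture(scope="session")
def femur_model(small_cohort):
    """Shape model built from the small cohort's MR femora."""
    _, knees, renders = small_cohort
    pop = ShapePopulation([renders[k.subject]["MR"][0] for k in knees])
    return build_shape_model(procrustes_align(pop), variance_retained=0.98)
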