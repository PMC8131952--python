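"""Shared fixtures: meshes and cohorts generated programmatically at test time."""

import numpy as np
import pytest

import surfage as sa


@pytest.fixture(scope="session")
def icosahedron():
    return sa.make_icosphere(0)


@pytest.fixture(scope="session")
def sphere_s3():
    """Small icosphere (642 vertices) for cheap geometric tests."""
    return sa.make_icosphere(3, 30.0)


@pytest.fixture(scope="session")
def default_mesh():
    """The default-scenario surface (2,562 vertices, radius 30 mm)."""
    from surfage.grid import DEFAULT_RADIUS_MM, DEFAULT_SUBDIVISIONS

    return sa.make_icosphere(DEFAULT_SUBDIVISIONS, DEFAULT_RADIUS_MM)


@pytest.fixture(scope="session")
def default_cohort(default_mesh):
    cohort, truth = sa.simulate_cohort(default_mesh, sa.CohortSpec(seed=1))
    return cohort, truth


def make_flat_grid(nx=61, ny=52, h=1.0):
    """Planar equilateral-triangle grid: the analytic-Gaussian test bed."""
    verts = []
    for j in range(ny):
        for i in range(nx):
            verts.append([i * h + (j % 2) * h / 2, j * h * np.sqrt(3) / 2, 0.0])
    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b, c, d = a + 1, a + nx, a + nx + 1
            if j % 2 == 0:
                tris += [[a, b, c], [b, d, c]]
            else:
                tris += [[a, b, d], [a, d, c]]
    return sa.SurfaceMesh(np.array(verts), np.array(tris), name="flat-grid")


@pytest.fixture(scope="session")
def flat_grid():
    return make_flat_grid()
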