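import numpy as np
import pytest

from aortaflow.hemodynamics import FluidConstants
from aortaflow.laplace import solve_laplace
from aortaflow.synthetic import make_cylinder

RADIUS_MM = 10.0
LENGTH_MM = 80.0


@pytest.fixture(scope="session")
def cylinder():
    """Coarse (2.5 mm) cylinder mesh + voxel grid, shared across tests."""
    mesh, grid = make_cylinder(RADIUS_MM, LENGTH_MM, 2.5, n_phases=4)
    return mesh, grid


@pytest.fixture(scope="session")
def cylinder_mesh(cylinder):
    return cylinder[0]


@pytest.fixture(scope="session")
def cylinder_lap(cylinder_mesh):
    return solve_laplace(cylinder_mesh)


@pytest.fixture(scope="session")
def fine_cylinder_mesh():
    mesh, _ = make_cylinder(RADIUS_MM, LENGTH_MM, 1.25, with_grid=False)
    return mesh


@pytest.fixture(scope="session")
def fine_cylinder_lap(fine_cylinder_mesh):
    return solve_laplace(fine_cylinder_mesh)


@pytest.fixture(scope="session")
def constants():
    return FluidConstants()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
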