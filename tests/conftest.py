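import numpy as np
import pytest

from rtetomo.angular import build_angular_grid
from rtetomo.mesh import mesh_disk, place_boundary_units
from rtetomo.phantom import OpticalCoefficients, Phantom, rasterize


@pytest.fixture(scope="session")
def grid8():
    return build_angular_grid(8, 0.7)


@pytest.fixture(scope="session")
def tiny_mesh():
    """~48-element disk, small enough for the direct global-system oracle."""
    return mesh_disk(10.0, 48, seed=5)


@pytest.fixture(scope="session")
def tiny_coeffs(tiny_mesh):
    return rasterize(Phantom(0.05, 2.0), tiny_mesh)


@pytest.fixture(scope="session")
def tiny_units(tiny_mesh, grid8):
    return place_boundary_units(tiny_mesh, 3, 3, grid8)


def two_triangle_mesh(shared_len=1.0):
    """Two triangles sharing one interior edge of the given length."""
    from rtetomo.mesh import build_trimesh

    nodes = np.array([[0.0, 0.0], [shared_len, 0.0],
                      [shared_len / 2, 0.9], [shared_len / 2, -0.9]])
    tris = np.array([[0, 1, 2], [0, 3, 1]])
    return build_trimesh(nodes, tris)


@pytest.fixture
def uniform_coeffs():
    def make(mesh, mua, mus):
        return OpticalCoefficients(np.full(mesh.n_elements, mua),
                                   np.full(mesh.n_elements, mus), mesh)
    return make
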