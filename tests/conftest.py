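import numpy as np
import pytest

from osteopair import TriangleMesh, uv_sphere, validate_mesh
from osteopair.synthetic import AssemblageConfig, generate_individual


@pytest.fixture
def tetra():
    """A regular-ish tetrahedron with outward-wound faces."""
    v = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                  [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return validate_mesh(TriangleMesh(id="tetra", vertices=v, faces=f))


@pytest.fixture
def cube():
    """Unit cube (mm), 8 vertices, 12 outward-wound faces."""
    v = np.array([[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0)
                  for z in (0.0, 1.0)])
    f = np.array([
        [0, 1, 3], [0, 3, 2],          # x = 0
        [4, 7, 5], [4, 6, 7],          # x = 1
        [0, 5, 1], [0, 4, 5],          # y = 0
        [2, 3, 7], [2, 7, 6],          # y = 1
        [0, 2, 6], [0, 6, 4],          # z = 0
        [1, 5, 7], [1, 7, 3],          # z = 1
    ])
    return validate_mesh(TriangleMesh(id="cube", vertices=v, faces=f))


@pytest.fixture(scope="session")
def sphere10():
    return uv_sphere(10.0, 10, 14, mesh_id="sphere10")


@pytest.fixture(scope="session")
def default_config():
    return AssemblageConfig()


@pytest.fixture(scope="session")
def individual_pair(default_config):
    """One synthetic individual at default asymmetry, random pose on."""
    return generate_individual(20260918, default_config, "i01", "males")


@pytest.fixture(scope="session")
def small_assemblage():
    """3 paired + 1 unpaired left, one group — 12 comparison cells."""
    from osteopair.synthetic import generate_assemblage
    cfg = AssemblageConfig(n_paired=3, n_unpaired_left=1, groups=("males",),
                           seed=11)
    return generate_assemblage(cfg)
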