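import numpy as np
import pytest
from hypothesis import settings

from efnet import (
    CohortSpec,
    Parcellation,
    SurfaceMesh,
    build_template_mesh,
    generate_cohort,
)
from efnet.networks import NETWORKS

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tetra_mesh() -> SurfaceMesh:
    """Smallest valid mesh: a regular-ish tetrahedron."""
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return SurfaceMesh(vertices=vertices, faces=faces)


@pytest.fixture(scope="session")
def small_mesh() -> SurfaceMesh:
    return build_template_mesh(2, radius=10.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared across tests (level-3 mesh, 6 subjects)."""
    spec = CohortSpec(
        master_seed=123,
        n_subjects=6,
        mesh_subdivision=3,
        n_timepoints=120,
        n_runs=2,
    )
    return generate_cohort(spec)


def eight_network_parcellation(n_vertices: int, rng=None) -> Parcellation:
    """Cyclic vertex->network labelling for connectivity unit tests."""
    if rng is None:
        parcels = np.arange(n_vertices) % 8
    else:
        parcels = rng.integers(0, 8, n_vertices)
        # guarantee >=2 vertices per network (self-exclusion needs a 2nd)
        parcels[:16] = np.tile(np.arange(8), 2)
    return Parcellation(
        vertex_parcel=parcels.astype(np.int64),
        parcel_network={i: NETWORKS[i] for i in range(8)},
    )
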