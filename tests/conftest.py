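import numpy as np
import pytest
import trimesh

from atriamorph import SyntheticSpec, generate_la_mesh
from atriamorph.mesh_core import SurfaceMesh, from_trimesh


@pytest.fixture(scope="session")
def icosphere32():
    """Analytic icosphere, radius 32 mm, with matching landmarks."""
    mesh, landmarks, truth = generate_la_mesh(SyntheticSpec(seed=0))
    return mesh, landmarks


@pytest.fixture(scope="session")
def unit_cube() -> SurfaceMesh:
    return from_trimesh(trimesh.creation.box(extents=(1.0, 1.0, 1.0)), name="cube")


@pytest.fixture(scope="session")
def deformed_atrium():
    """A generic deformed noisy atrium used by invariance tests."""
    spec = SyntheticSpec(amplitudes=(2, -1, 3, -2, 1, 2.5), noise_sigma=0.3, seed=11)
    return generate_la_mesh(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
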