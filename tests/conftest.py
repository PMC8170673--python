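import numpy as np
import pytest

from fus3d.geometry import RigidTransform
from fus3d.phantom import PhantomSpec, generate_phantom


def random_rigid(rng: np.random.Generator) -> RigidTransform:
    """Uniform-ish random proper rigid transform for property tests."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return RigidTransform(Q, rng.normal(scale=100.0, size=3))


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
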