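import numpy as np
import pytest

from bgcnn.sphere_geometry import build_icosahedron, build_kernel_grid


@pytest.fixture(scope="session")
def chart():
    return build_icosahedron()


@pytest.fixture(scope="session")
def grid():
    return build_kernel_grid(0.6, 5, 2, include_center=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
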