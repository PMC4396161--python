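import numpy as np
import pytest

from npcable import TriangleMesh, generate_ellipse_mesh


@pytest.fixture(scope="session")
def unit_right_triangle():
    """Single right triangle (0,0), (1,0), (0,1) — closed-form element
    matrices are known by hand."""
    return TriangleMesh(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
                        np.array([[0, 1, 2]]))


@pytest.fixture(scope="session")
def disc_mesh():
    return generate_ellipse_mesh(1.0, 1.0, 0.1)


@pytest.fixture(scope="session")
def ellipse_mesh():
    """Published cell geometry (a=2, b=1) at the coarsest tabulated size."""
    return generate_ellipse_mesh(2.0, 1.0, 0.2)


@pytest.fixture(scope="session")
def coarse_ellipse_mesh():
    return generate_ellipse_mesh(2.0, 1.0, 0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(20140)
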