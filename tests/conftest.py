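import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retractx.crack import CrackGeometry
from retractx.mesh import build_hex_mesh
from retractx.volume import LabelVolume

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.cross(np.eye(3), axis)
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


@pytest.fixture
def unit_affine():
    return np.eye(4)


@pytest.fixture
def cube_mesh():
    """3x3x3-element cube, 15 mm side, 5 mm elements."""
    lab = LabelVolume(np.ones((15, 15, 15), dtype=np.uint8), np.eye(4))
    return build_hex_mesh(lab, 5.0)


@pytest.fixture
def bar_mesh():
    """4x2x2-element bar (20 x 10 x 10 mm), 5 mm elements."""
    lab = LabelVolume(np.ones((20, 10, 10), dtype=np.uint8), np.eye(4))
    return build_hex_mesh(lab, 5.0)


@pytest.fixture
def simple_crack():
    """Vertical plane x = 10, mouth on top (z = 40), front at z = 10."""
    return CrackGeometry((10.0, 20.0, 40.0), (1, 0, 0), (0, 0, -1), 60.0, 30.0)


@pytest.fixture
def far_crack():
    """A crack far outside any small test mesh."""
    return CrackGeometry((1e4, 0.0, 0.0), (1, 0, 0), (0, 0, -1), 1.0, 1.0)
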