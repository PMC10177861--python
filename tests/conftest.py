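import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ribsuppress.phantom import PhantomSpec, generate
from ribsuppress.st_transform import Contour

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def square_contour():
    """CCW unit-ish square whose bottom edge (0,0)->(10,0) has inward normal +y."""
    return Contour([(0, 0), (10, 0), (10, 10), (0, 10)])


@pytest.fixture
def thin_rect_contour():
    """Long thin rectangle: thickness 10, length 100."""
    return Contour([(0, 0), (100, 0), (100, 10), (0, 10)])


def regular_polygon(n: int, radius: float, center=(0.0, 0.0)) -> Contour:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([center[0] + radius * np.cos(th),
                                    center[1] + radius * np.sin(th)]))


@pytest.fixture
def single_rib_phantom():
    return generate(PhantomSpec(size=(128, 128), n_ribs=1, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
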