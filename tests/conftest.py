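import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dimerframe.synthetic import synthetic_dimer

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dimer():
    """Exactly C2-symmetric synthetic dimer at a 142° α2-α2 angle."""
    return synthetic_dimer(angle=142.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
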