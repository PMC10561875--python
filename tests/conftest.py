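import numpy as np
import pytest

from costgo.plant import PointMassParams, build_plant


@pytest.fixture
def params():
    """The standard unit point mass: m = G = 1, tau = 60 ms, dt = 10 ms."""
    return PointMassParams(m=1.0, G=1.0, tau=0.06, dt=0.01)


@pytest.fixture
def plant(params):
    """Noise-free delayed plant with the standard 50 ms (5-step) delay."""
    return build_plant(params, h=5)


@pytest.fixture
def noisy_plant(params):
    return build_plant(params, h=5, motor_noise=0.1,
                       sensory_noise=np.full(16, 0.01))
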