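import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from demonpump import PumpParameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def draw_random_params(rng: np.random.Generator, n: int, *, with_delta: bool = True):
    """Random valid parameter sets: log-uniform k in [0.01, 100] and
    concentrations in [0.001, 10] with C_h > C_l > 0."""
    k_h = 10.0 ** rng.uniform(-2, 2, n)
    k_l = 10.0 ** rng.uniform(-2, 2, n)
    c = 10.0 ** rng.uniform(-3, 1, (n, 2))
    C_h, C_l = c.max(axis=1), c.min(axis=1)
    delta = rng.uniform(-1, 1, n) if with_delta else np.zeros(n)
    return [
        PumpParameters(delta=d, k_h=a, k_l=b, C_h=h, C_l=l)
        for d, a, b, h, l in zip(delta, k_h, k_l, C_h, C_l)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20230414)


@pytest.fixture
def reference_params():
    """The worked parameter point used throughout: k = 1, C_h = 2, C_l = 1."""
    return PumpParameters(delta=1.0, k_h=1.0, k_l=1.0, C_h=2.0, C_l=1.0)
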