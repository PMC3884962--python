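import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_noisefree_phantom():
    """Noise-free box phantom with well-separated constants."""
    from dcac.phantom import PhantomSpec, generate_phantom

    spec = PhantomSpec(shape=(8, 16, 16), geometry="box", c1=10.0, c2=2.0,
                       gamma=1.0, sigma=0.0, seed=0)
    return generate_phantom(spec)
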