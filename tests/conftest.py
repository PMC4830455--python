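import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160413)


@pytest.fixture(scope="session")
def small_phantom():
    """A small, fast phantom pair with identity misalignment and no noise."""
    from coralct.phantom import PhantomSpec, make_phantom_pair

    spec = PhantomSpec(dims=(48, 64, 64), margin=10, seed=7, noise_sd=0.0)
    pre, post, truth = make_phantom_pair(spec)
    return pre, post, truth, spec


@pytest.fixture()
def cuboid_mask():
    from coralct.volume_io import BinaryVolume

    m = np.zeros((24, 30, 30), dtype=bool)
    m[4:20, 5:25, 5:25] = True
    return BinaryVolume(m, 100.0)
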