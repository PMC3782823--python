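import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mammogc import PhantomSpec, generate_phantom  # noqa: E402


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default 96x80 noiseless phantom with a mass and an artifact."""
    return generate_phantom(PhantomSpec(has_mass=True, has_artifact=True, rng_seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Moderately noisy phantom (SD 5 gray levels) with a mass."""
    return generate_phantom(PhantomSpec(noise_sd=5.0, has_mass=True, rng_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
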