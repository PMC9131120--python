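import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from colonyoptics import ColonyOpticalParams, simulate_spectral_map  # noqa: E402


@pytest.fixture(scope="session")
def noiseless_single_order_map():
    """Noiseless, fully aligned, first-order-only map (d = 425 nm)."""
    params = ColonyOpticalParams(
        d=425.0, noise_sd=0.0, aligned_fraction=1.0, orders=(1,), seed=0
    )
    return params, simulate_spectral_map(params)


@pytest.fixture(scope="session")
def noisy_map():
    """Moderate-noise two-order map at the ordered-colony preset."""
    params = ColonyOpticalParams(d=425.0, noise_sd=0.05, seed=11)
    return params, simulate_spectral_map(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
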