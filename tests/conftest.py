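import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hvcurve import SimulationConfig, WeibullParams, generate_vc_observations

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: The fitted curve every worked example uses: scale 2.23 MPa, shape 2.50.
FITTED = WeibullParams(a=2.23, b=2.50)


@pytest.fixture
def fitted_params() -> WeibullParams:
    return FITTED


@pytest.fixture
def noiseless_observations():
    """Exact curve values of the fitted parameters on the 24-level schedule."""
    return generate_vc_observations(
        SimulationConfig(true_params=FITTED, noise_sd=0.0, n_samples=1)
    )


@pytest.fixture
def noisy_observations():
    """One noisy synthetic curve (sd 0.02) under a fixed seed."""
    return generate_vc_observations(
        SimulationConfig(true_params=FITTED, noise_sd=0.02, n_samples=1, seed=42)
    )
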