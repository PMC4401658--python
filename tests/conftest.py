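import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def params():
    """Above-Tc landscape used throughout: rho = T/Tc ~ 0.9."""
    from bindscape import LandscapeParams

    return LandscapeParams(mean_energy=-6.0, roughness=2.0, num_states=100)


@pytest.fixture
def glassy_params():
    """Below-Tc landscape with T/Tc = 0.5 (Tc = 1, T = 0.5)."""
    from bindscape import LandscapeParams

    return LandscapeParams(mean_energy=0.0, roughness=2.0, entropy=2.0, temperature=0.5)
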