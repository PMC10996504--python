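import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def trained_tactile_session():
    """One small trained tactile-cohort session shared across tests."""
    from thalattn.synthetic_session import PopulationParams, simulate_population

    return simulate_population(
        6, "tactile", seed=11,
        params=PopulationParams(n_per_modality=30))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
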