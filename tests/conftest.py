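import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from refill_cea.cohort_simulator import default_config, generate_cohort
from refill_cea.model_params import paper_model


@pytest.fixture(scope="session")
def model():
    """The published base-case decision model."""
    return paper_model()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (578 PRP / 251 SOC)."""
    return generate_cohort(default_config(seed=123))
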