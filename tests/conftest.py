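import pytest
from hypothesis import HealthCheck, settings

import cvdcheck as cv

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    """Shipped default configuration (calibrated emulation)."""
    return cv.load_config()


@pytest.fixture(scope="session")
def base_report(config):
    """Deterministic base-case run, shared across tests (pure function)."""
    return cv.run_base_case(config)


@pytest.fixture(scope="session")
def male_params(config):
    return config.markov_parameters("male")


@pytest.fixture(scope="session")
def male_utils(config):
    return config.utility_set("male")


@pytest.fixture(scope="session")
def male_costs(config):
    return config.cost_set("male")
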