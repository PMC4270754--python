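import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants():
    from frickedose.config import load_constants

    return load_constants()


@pytest.fixture(scope="session")
def coeffs(constants):
    return constants.coefficients


@pytest.fixture(scope="session")
def default_budget():
    from frickedose.budget import load_budget

    return load_budget()
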