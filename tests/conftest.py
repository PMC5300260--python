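import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tomato():
    from graftsim import TOMATO

    return TOMATO


@pytest.fixture
def watermelon():
    from graftsim import WATERMELON

    return WATERMELON


@pytest.fixture
def peaked_scenario():
    """Small single-peak scenario used across simulator tests."""
    from graftsim import make_scenario

    return make_scenario("single_peak", 20, 120, 6, 1, 10)
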