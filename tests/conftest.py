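import pytest
from hypothesis import settings

from ovreserve import GridSpec, RadiationParams, default_decay, simulate_grid

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def decay():
    return default_decay()


@pytest.fixture(scope="session")
def rad():
    return RadiationParams()


@pytest.fixture(scope="session")
def full_grid(decay, rad):
    """Default simulation grid: ages 10-50, doses 0.5 Gy steps to sterilizing."""
    return simulate_grid(GridSpec(), decay, rad)
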