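import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from parkaccess import (
    DecaySpec,
    ModeMix,
    ScenarioConfig,
    TravelCostMatrix,
    generate_city,
    generate_mode_costs,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def matrix_from(demand, supply, cost, mode="m"):
    """Wrap an aligned cost array as a TravelCostMatrix."""
    return TravelCostMatrix(
        mode=mode,
        origin_ids=[s.site_id for s in demand],
        dest_ids=[s.site_id for s in supply],
        cost=np.asarray(cost, float),
    )


@pytest.fixture(scope="session")
def default_city():
    return generate_city(ScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def default_costs(default_city):
    return generate_mode_costs(default_city)


@pytest.fixture
def gaussian39():
    return DecaySpec(kind="gaussian", threshold=39.0)


@pytest.fixture
def default_mix():
    return ModeMix.default()
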