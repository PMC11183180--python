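import numpy as np
import pytest
from hypothesis import settings

import seedsource as ss

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig2():
    """Two-stage reference life cycle and its run defaults."""
    vital, defaults = ss.figure2_fixture()
    return vital, defaults


@pytest.fixture(scope="session")
def fig2_vital(fig2):
    return fig2[0]


@pytest.fixture(scope="session")
def typical_lh(fig2_vital):
    return ss.typical_life_history_from_rates(fig2_vital, 60)


@pytest.fixture(scope="session")
def intermediate_scenario():
    return ss.ClimateScenario.preset(T0=0.0, warming="intermediate", H=60)


@pytest.fixture(scope="session")
def intermediate_series(intermediate_scenario):
    return ss.temperature_series(intermediate_scenario)


@pytest.fixture(scope="session")
def three_stage_vital():
    """Small three-stage ladder used for cross-module equivalence checks."""
    return ss.VitalRates(s_max=np.array([0.7, 0.85, 0.95]), g=np.array([0.4, 0.3]))


def random_conformant_vital(rng, n):
    s = rng.uniform(0.05, 0.99, size=n)
    g = rng.uniform(0.01, 0.99, size=n - 1)
    return ss.VitalRates(s_max=s, g=g)
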