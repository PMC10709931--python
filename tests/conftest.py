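import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mealtrace import GlucoseSeries, SimulationConfig, simulate_participant

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

T0 = pd.Timestamp("2022-03-01 00:00")
FIVE_MIN = pd.Timedelta(minutes=5)


def make_series(values, start=T0, participant_id="p1", interval=FIVE_MIN):
    """Series directly from gridded values; NaN entries are gaps."""
    return GlucoseSeries(participant_id, start, interval, np.asarray(values, float))


@pytest.fixture(scope="session")
def sim_default():
    """One 28-day participant at the default study conditions (seed 7)."""
    return simulate_participant(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def sim_short():
    """A 12-day participant for faster pipeline tests."""
    return simulate_participant(SimulationConfig(n_days=12, seed=11))
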