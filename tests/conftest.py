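import numpy as np
import pytest

from canopygc import (
    ExperimentConfig,
    SamplingEvent,
    make_event_schedule,
    simulate_trial,
)


@pytest.fixture(scope="session")
def default_config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def schedule(default_config):
    return make_event_schedule(default_config.schedule)


@pytest.fixture(scope="session")
def noon_event(schedule):
    """High-light dry afternoon event."""
    return schedule[0]


@pytest.fixture(scope="session")
def dark_event():
    """Zero-radiation dry event (not part of the default schedule)."""
    return SamplingEvent(event_id=99, clock_label="00:00 dX",
                         solar_radiation=0.0, dew=False)


@pytest.fixture(scope="session")
def dew_event(schedule):
    ev = next(e for e in schedule if e.dew)
    return ev


@pytest.fixture(scope="session")
def default_trial(default_config):
    """Default 192-plot / 99-genotype trial, seed 7."""
    return simulate_trial(default_config.trial, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
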