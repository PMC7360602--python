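import datetime as dt

import numpy as np
import pytest

from cagedose import (
    Group,
    MouseProfile,
    SystemConfig,
    default_colony,
    run_colony,
)

START = dt.datetime(2020, 1, 1, 0, 0, 0)


@pytest.fixture
def config() -> SystemConfig:
    return SystemConfig()


@pytest.fixture
def treatment_profile() -> MouseProfile:
    return MouseProfile(rfid_tag="T001", group=Group.TREATMENT, dose_mg_per_kg=1.0)


@pytest.fixture
def control_profile() -> MouseProfile:
    return MouseProfile(rfid_tag="C001", group=Group.CONTROL)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_run():
    """The scaled-down study analogue: 4 mice (3 treatment, 1 control)
    over 14 simulated days at default noise.  Shared across tests because
    the full sensor-stream simulation is the expensive part."""
    run = default_colony(n_mice=4, n_treatment=3, days=14, seed=20200101)
    return run, run_colony(run)
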