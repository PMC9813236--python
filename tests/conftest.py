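import numpy as np
import pytest

from stepgaze import GaitParams, ObserverModel, SessionConfig, generate_session
from stepgaze.synthetic_cohort import WalkwayGeometry
from stepgaze.trial_design import TrialSpec

THRESHOLDS = {"R1": 4.0, "L1": 4.3, "R2": 3.2, "L2": 3.6}


@pytest.fixture(scope="session")
def default_schedule():
    return generate_session(SessionConfig(seed=5), THRESHOLDS)


@pytest.fixture
def observer():
    return ObserverModel()


@pytest.fixture
def gait():
    return GaitParams()


@pytest.fixture
def geometry(gait):
    return WalkwayGeometry.from_gait(gait)


@pytest.fixture
def crossing_trial():
    return TrialSpec(trial_id=7, block=0, condition="crossing", cue="right_arrow",
                     gabor_location="R1", gabor_side="right", gabor_orientation=4.0)


@pytest.fixture
def stationary_trial():
    return TrialSpec(trial_id=8, block=0, condition="stationary",
                     cue="horizontal_bar", gabor_location="L1",
                     gabor_side="left", gabor_orientation=4.3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
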