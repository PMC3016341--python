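import numpy as np
import pytest

from mousemetab import (
    CHOW,
    HIGH_FAT,
    ActivitySchedule,
    BodyState,
    IntakeSchedule,
    ModelParameters,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture
def init_state():
    """Typical 3-month-old male C57BL/6: 27 g body weight, 4 g fat."""
    return BodyState(FM=4.0, FFM=23.0)


@pytest.fixture
def two_switch_activity():
    """High fat from day 20, back to chow at day 60, default coefficients."""
    return ActivitySchedule.two_switch(20.0, 60.0)


@pytest.fixture
def hf_episode_intake():
    """Chow -> high-fat -> chow intake matching ``two_switch_activity``."""
    return IntakeSchedule(
        np.array([0.0, 20.0, 27.0, 60.0, 67.0]),
        np.array([12.0, 15.0, 13.5, 6.5, 11.5]),
        (CHOW, HIGH_FAT, HIGH_FAT, CHOW, CHOW),
        baseline_EI=12.0,
    )
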