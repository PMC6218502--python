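import numpy as np
import pytest

from fallkit.core_io import Location
from fallkit.synthetic_data import (
    GaitProfile,
    simulate_battery,
    simulate_cohort_features,
    simulate_tug,
    table3_cohort_spec,
)

RATE = 100.0


@pytest.fixture(scope="session")
def battery():
    """One complete noiseless-ish synthetic battery (expensive; share it)."""
    sessions, logs, truths = simulate_battery(seed=42)
    return sessions, logs, truths


@pytest.fixture(scope="session")
def cohort_df():
    """Feature-level cohort with the published group parameters (n=114/82)."""
    return simulate_cohort_features(table3_cohort_spec(seed=7))


@pytest.fixture()
def clean_tug():
    profile = GaitProfile(n_steps=10, stride_time=1.0, noise_sd=0.0, turn_duration=2.0)
    session, gt = simulate_tug(profile, seed=1)
    return session, gt


def shank_gyro(session, side):
    loc = Location.LEFT_LOWER_LEG if side == "left" else Location.RIGHT_LOWER_LEG
    return session.recording(loc).gyro[:, 1]
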