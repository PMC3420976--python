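import numpy as np
import pytest

from loomtau import ApproachStimulus, generate_trace


@pytest.fixture
def stim():
    """Default sphere approach: R = 5 cm, v = 2 m/s, contact at 3 s."""
    return ApproachStimulus(half_size_R=0.05, speed_v=2.0, collision_time_tc=3.0, dt=1e-3)


@pytest.fixture
def small_angle_stim():
    """Stimulus with R/d0 = 0.005, where tau ~= t_c - t holds tightly."""
    return ApproachStimulus(half_size_R=0.01, speed_v=1.0, collision_time_tc=2.0, dt=1e-3)


@pytest.fixture
def clean_trace(stim):
    return generate_trace(stim, 0.0, 2.9)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
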