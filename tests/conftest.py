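import numpy as np
import pytest

from graspadapt import schedules as sched
from graspadapt.simulate import SimParticipant, TrajectorySpec


@pytest.fixture
def abrupt_spec():
    return sched.ScheduleSpec(schedule_kind="abrupt", magnitude=12.0, n_trials=24,
                              baseline_len=4)


@pytest.fixture
def sinus_spec():
    return sched.ScheduleSpec(schedule_kind="sinusoidal", magnitude=12.0, n_trials=36,
                              n_cycles=3)


@pytest.fixture
def abrupt_schedule(abrupt_spec):
    return sched.make_abrupt_schedule(abrupt_spec, [40.0] * 24)


@pytest.fixture
def sinus_schedule(sinus_spec):
    return sched.make_sinusoidal_schedule(sinus_spec, [44.0] * 36)


@pytest.fixture
def quiet_participant():
    """Noise-free generator at the reference parameter point."""
    return SimParticipant(motor_noise_sd=0.0, obs_sigma=0.0, seed=11)


@pytest.fixture
def main_traj_spec():
    return TrajectorySpec.for_experiment("main")


@pytest.fixture
def rng():
    return np.random.default_rng(20240724)
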