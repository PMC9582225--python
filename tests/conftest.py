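import numpy as np
import pytest

from osn_stream.model import AnalysisConfig, SchedulePanel, StimulusSchedule


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def sched15():
    """In vivo style schedule: 20 s trial, onset 4 s, 1 s stimulus, 15 Hz."""
    return StimulusSchedule(
        stimulus_label="odorA_0.01", odorant="odorA", concentration=0.01,
        is_blank=False, onset_s=4.0, duration_s=1.0,
        trial_length_s=20.0, sampling_rate_hz=15.0,
    )


@pytest.fixture
def panel15(sched15):
    blank = StimulusSchedule(
        stimulus_label="blank", odorant="blank", concentration=0.0,
        is_blank=True, onset_s=4.0, duration_s=1.0,
        trial_length_s=20.0, sampling_rate_hz=15.0,
    )
    return SchedulePanel({sched15.stimulus_label: sched15, "blank": blank})


def make_step_trace(schedule, baseline=100.0, step=50.0, step_duration_s=2.0):
    """Constant baseline with a rectangular step starting right after onset."""
    n = schedule.n_samples
    t = np.arange(n) / schedule.sampling_rate_hz
    trace = np.full(n, baseline)
    on = (t > schedule.onset_s) & (t <= schedule.onset_s + step_duration_s)
    trace[on] += step
    return trace
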