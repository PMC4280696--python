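import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from solereflex import emg, stimulus, synthetic as syn


@pytest.fixture(scope="session")
def default_profile():
    return syn.SubjectProfile()


@pytest.fixture(scope="session")
def slow_heel_schedule():
    """Twenty slow heel pulses at 3.5 bar, compressed 3 s spacing."""
    return stimulus.single_pulse_protocol(
        pressures=[3.5], rise_speeds=["slow"], locations=["heel"],
        reps=20, interval=3.0, pulse_duration=0.8, seed=11, lead_in_rest=2.0,
    )


@pytest.fixture(scope="session")
def certain_session(slow_heel_schedule):
    """Session where every stimulus evokes a reflex (probability 1)."""
    profile = syn.SubjectProfile(reflex_probability=1.0)
    sess = syn.gen_session(profile, slow_heel_schedule, seed=21)
    return sess, emg.preprocess(sess.emg)


def rectified_recording(values, sample_rate=1200.0, channel="TA"):
    """Wrap explicit rectified sample values in an EmgRecording."""
    values = np.asarray(values, float)
    times = np.arange(len(values)) / sample_rate
    chans = {"TA": values.copy(), "SOL": values.copy()}
    chans[channel] = values
    return emg.EmgRecording(times=times, channels=chans, state="rectified")
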