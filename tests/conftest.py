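import numpy as np
import pytest

from phasesleep.recording import EEGRecording
from phasesleep.synth import CohortSpec, StageProfile, default_profiles, generate_cohort

#: All four bands at zero coupling — channels are independent noise.
ZERO_COUPLING = {"delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Cheap cohort geometry used across tests: 4 subjects, 6 channels."""
    return CohortSpec(n_subjects=4, segment_length_s=100.0, fs=100.0,
                      n_channels=6, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(default_profiles(), small_spec)


@pytest.fixture()
def sine_recording():
    """Two-channel 10 Hz sinusoid with a quarter-cycle lag between channels."""
    fs = 250.0
    t = np.arange(int(120 * fs)) / fs
    data = np.vstack([np.cos(2 * np.pi * 10 * t),
                      np.cos(2 * np.pi * 10 * t - np.pi / 2)])
    return EEGRecording(data=data, fs=fs, channel_names=("a", "b"),
                        stage="W", subject_id="S1")


def make_profile(stage="W", coupling=None, **kwargs):
    strengths = dict(ZERO_COUPLING)
    if coupling:
        strengths.update(coupling)
    return StageProfile(stage=stage, coupling_strength=strengths, **kwargs)
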