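import numpy as np
import pytest

from eegscreen.io import Recording
from eegscreen.synth import SpectralProfile, _default_weights, default_profiles, generate_recording


@pytest.fixture(scope="session")
def healthy_profile():
    return default_profiles()["healthy"]


@pytest.fixture(scope="session")
def short_recording(healthy_profile):
    """10 s of clean synthetic resting EEG at 512 Hz."""
    return generate_recording(healthy_profile, fs=512, duration_s=10, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_tone(freq, fs=512.0, duration_s=2.0, amplitude=1.0, subject_id="tone"):
    t = np.arange(int(round(fs * duration_s))) / fs
    return Recording(subject_id, amplitude * np.sin(2 * np.pi * freq * t), fs)
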