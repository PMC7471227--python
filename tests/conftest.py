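import numpy as np
import pytest
from hypothesis import settings

from mitopo.montage import standard_montage_22
from mitopo.preprocess import RawRecording, TrialEpoch

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def montage22():
    return standard_montage_22()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(montage, fs=250.0, n_trials=3, rng=None, labels=None):
    """Small white-noise recording with one event per 7 s trial."""
    rng = rng or np.random.default_rng(0)
    n_samp = int(round(7.0 * fs))
    data = rng.standard_normal((len(montage), n_trials * n_samp))
    labels = labels or ["left", "right", "left"][:n_trials]
    events = [(k * n_samp, labels[k % len(labels)]) for k in range(n_trials)]
    return RawRecording(data=data, fs=fs, montage=montage, events=events)


@pytest.fixture()
def small_recording(montage22, rng):
    return make_recording(montage22, rng=rng)


def tone_trial(montage, freq=10.0, fs=250.0, amp=1.0, channel=None, rng=None,
               label="left"):
    """7 s trial of weak noise with a tone on one channel (or all)."""
    rng = rng or np.random.default_rng(1)
    n = int(round(7.0 * fs))
    t = np.arange(n) / fs
    data = 0.01 * rng.standard_normal((len(montage), n))
    tone = amp * np.sin(2 * np.pi * freq * t)
    if channel is None:
        data += tone
    else:
        data[channel] += tone
    return TrialEpoch(data=data, label=label, fs=fs)
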