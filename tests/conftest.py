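import numpy as np
import pandas as pd
import pytest

from iseeg.io import Recording
from iseeg.synthetic_data import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Cheap generator settings for unit tests."""
    return GeneratorConfig(n_subjects=3, pulses_per_level=2, seed=7)


def make_recording(data, fs=1000.0, labels=None):
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[1])]
    return Recording(data=data, sampling_rate=fs, channel_labels=labels)


def make_events(onsets, energies=None, ratings=None):
    onsets = np.asarray(onsets, dtype=float)
    n = len(onsets)
    return pd.DataFrame({
        "trial_index": np.arange(n),
        "onset_s": onsets,
        "energy_J": energies if energies is not None else np.full(n, 2.0),
        "rating": ratings if ratings is not None else np.full(n, 5, dtype=int),
    })


@pytest.fixture
def two_event_recording():
    """10 s ISI pair inside a zero recording at 1 kHz (plus padding)."""
    rec = make_recording(np.zeros(30_000))
    events = make_events([5.0, 15.0])
    return rec, events
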