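import numpy as np
import pandas as pd
import pytest

import mindstate as ms
from mindstate import experiments as ex
from mindstate import synthgen as sg


@pytest.fixture(scope="session")
def small_recording():
    """One short synthetic session shared by read-only tests."""
    return sg.generate_session(ex.small_session_config(7))


@pytest.fixture(scope="session")
def truth_epochs(small_recording):
    """5-s ground-truth state epochs of the shared session."""
    return ms.epoch_truth_segments(small_recording, window_s=5.0, max_per_state=6)


@pytest.fixture(scope="session")
def stim_epochs(small_recording):
    """Baseline-corrected, probe-labeled stimulus epochs of the shared session."""
    stim = ms.epoch_stimuli(small_recording)
    stim = ms.label_trials(stim, small_recording)
    return ms.baseline_correct(stim)


def make_epochs(data, fs=250.0, window=(-0.25, 0.75), metadata=None, channel_names=None):
    """Tiny EpochSet factory for synthetic-array tests."""
    n_t, n_c, _ = data.shape
    if metadata is None:
        metadata = pd.DataFrame({"subject": ["S0"] * n_t, "block": np.zeros(n_t, int)})
    if channel_names is None:
        channel_names = [f"c{i}" for i in range(n_c)]
    return ms.EpochSet(data=data, fs=fs, window=window, metadata=metadata,
                       channel_names=channel_names)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
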