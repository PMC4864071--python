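import numpy as np
import pytest

from dtwspec import EEGRecording, TrialTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """4 channels x 400 samples of structured noise at 50 Hz."""
    data = rng.standard_normal((4, 400))
    return EEGRecording(data=data, rate=50.0, subject_id="fix")


@pytest.fixture
def simple_trials():
    return TrialTable(
        trial_sample=np.array([100, 200, 300]),
        block_id=np.array([0, 1, 2]),
        block_type=["task", "rest", "task"],
    )
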