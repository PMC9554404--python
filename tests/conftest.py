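import numpy as np
import pandas as pd
import pytest

from wristpa.signal_io import RawRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20210301)


def make_recording(samples, start="2021-03-03 00:00:00", rate=50.0, pid="T000"):
    return RawRecording(pid, pd.Timestamp(start), rate, np.asarray(samples, float))


@pytest.fixture
def still_recording():
    """60 s of exact (0, 0, 1) at 50 Hz."""
    n = 3000
    samples = np.zeros((n, 3))
    samples[:, 2] = 1.0
    return make_recording(samples)
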