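import numpy as np
import pytest

from fceeg.io import Recording
from fceeg.montage import default_montage


@pytest.fixture(scope="session")
def montage64():
    return default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def make_recording(data, fs=250.0, names=None, **kw) -> Recording:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data=data, sampling_rate=fs, channel_names=list(names), **kw)


def sine(freq, duration, fs=250.0, amp=1.0, phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)
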