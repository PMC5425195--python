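import numpy as np
import pytest

from emgonset.io import EmgRecording
from emgonset.synth import spliced_trial_from_snr


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def spliced_snr20():
    """One spliced 3072-sample trial at amplitude SNR ~20 (study geometry)."""
    return spliced_trial_from_snr(20.0, fs=2048.0, seed=7)


def make_recording(x, fs=2048.0, **kw) -> EmgRecording:
    return EmgRecording(samples=np.asarray(x, dtype=float), fs=fs, **kw)
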