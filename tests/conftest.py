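import numpy as np
import pytest

from lfpdecode import LfpRecording, default_fixture


@pytest.fixture(scope="session")
def fixture_session():
    """The bundled synthetic session (120 s, 6 units, 8 channels)."""
    return default_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_lfp(samples, fs=100.0, t_start=0.0):
    n_ch = np.atleast_2d(samples).shape[1]
    return LfpRecording(
        samples=samples, fs=fs, channel_ids=[f"ch{i}" for i in range(n_ch)], t_start=t_start
    )
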