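import numpy as np
import pytest

from speechmood.pitch import estimate_pitch
from speechmood.synth import render, standard_script


@pytest.fixture(scope="session")
def fixture30():
    """The standard 30-s running-speech fixture: script, rendering, pitch track."""
    script = standard_script(30.0)
    res = render(script, rate=48000.0, seed=7)
    track = estimate_pitch(res.audio)
    return script, res, track


@pytest.fixture(scope="session")
def fixture3():
    """A short 3-s fixture for quick end-to-end tests."""
    script = standard_script(3.0)
    res = render(script, rate=48000.0, seed=11)
    track = estimate_pitch(res.audio)
    return script, res, track


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
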