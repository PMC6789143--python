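import numpy as np
import pytest

from cardiodyn import BeatSimSpec, simulate_waveform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_1hz_waveform():
    """20 beats in 20 s at 100 fps, amplitudes 20/15 µm/s, no noise."""
    spec = BeatSimSpec(bpm=60.0, duration_s=20.0, fps=100.0, seed=0)
    w, truth = simulate_waveform(spec)
    return w, truth
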