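import numpy as np
import pytest

from swarmspeech.audio_features import AudioSignal, MfccConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_cfg():
    return MfccConfig()


@pytest.fixture
def one_second_tone():
    sr = 16000
    t = np.arange(sr) / sr
    return AudioSignal(samples=0.5 * np.sin(2 * np.pi * 440.0 * t), sample_rate=sr)


@pytest.fixture
def noise_signal(rng):
    return AudioSignal(samples=0.1 * rng.standard_normal(16000), sample_rate=16000)


def make_sequences(n, t=64, c=4, shift=1.0, seed=0):
    """Two-class sequence sets for classifier tests: class 1 gets a slow
    sinusoidal bump on channel 0 and a mean shift on channel 1."""
    gen = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = gen.normal(size=(n, t, c))
    bump = shift * np.sin(np.linspace(0, 2 * np.pi, t))
    x[y == 1, :, 0] += bump
    x[y == 1, :, 1] += shift * 0.5
    return x, y
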