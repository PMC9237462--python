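import numpy as np
import pytest

from sylentrain.audio_envelope import Envelope


@pytest.fixture
def triangular_envelope():
    """Piecewise-linear fixture at 1 kHz: rise 0->1 over 100 ms, fall 1->0
    over 150 ms (251 samples, so the rise holds exactly 100 derivative steps
    and the fall 150)."""
    rise = np.linspace(0.0, 1.0, 101)
    fall = np.linspace(1.0, 0.0, 151)[1:]
    return Envelope(np.concatenate([rise, fall]), 1000.0, stage="summed")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
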