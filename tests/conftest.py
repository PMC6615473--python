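import numpy as np
import pytest
from hypothesis import settings

from memnet import glyph_set
from memnet.encode import image_to_spikes

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def glyphs():
    """The ten canonical digit glyphs."""
    return glyph_set()


@pytest.fixture(scope="session")
def spike_sequences(glyphs):
    """Encoded spike sequences for the ten glyphs (power encoder)."""
    return [image_to_spikes(img) for img in glyphs]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
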