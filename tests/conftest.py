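import numpy as np
import pytest

from mucoh.envelope import extract_envelope
from mucoh.synth.audio import gen_music_audio


@pytest.fixture(scope="session")
def tonal_audio():
    """80-s excerpt with a pure 2 Hz sinusoidal modulator (no modulator noise)."""
    return gen_music_audio(80.0, 16000.0, modulator_freqs=(2.0,),
                           mod_noise_weight=0.0, seed=7, audio_id="tone2hz")


@pytest.fixture(scope="session")
def default_audio():
    return gen_music_audio(78.0, 16000.0, seed=3, audio_id="default")


@pytest.fixture(scope="session")
def default_envelope(default_audio):
    return extract_envelope(default_audio)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
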