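import numpy as np
import pytest

from songsim.synth import SyllableParams, generate_syllable
from songsim.audio import preprocess_syllable


@pytest.fixture(scope="session")
def tone_syllable():
    """Pure 600 Hz tone, 150 ms."""
    return generate_syllable(
        SyllableParams(duration=0.15, f0_start=600.0, f0_end=600.0,
                       n_harmonics=1, noise_fraction=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def noise_syllable():
    """Pure broadband noise, 150 ms."""
    return generate_syllable(
        SyllableParams(duration=0.15, noise_fraction=1.0, seed=12)
    )


@pytest.fixture(scope="session")
def tone_preprocessed(tone_syllable):
    return preprocess_syllable(tone_syllable)


@pytest.fixture(scope="session")
def noise_preprocessed(noise_syllable):
    return preprocess_syllable(noise_syllable)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
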