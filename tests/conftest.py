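import numpy as np
import pytest

from fawfs.synthetic_data import EEGSpec, TabularSpec, make_classification_dataset, make_synthetic_eeg


@pytest.fixture(scope="session")
def planted_dataset():
    """Strong planted signal: 300 samples, 20 features, 5 informative."""
    return make_classification_dataset(TabularSpec(300, 20, 5, 2.0, seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset for fast wrapper/pipeline tests."""
    return make_classification_dataset(TabularSpec(120, 10, 3, 2.0, seed=7))


@pytest.fixture()
def blink_fixture():
    """Contaminated/clean EEG pair with 5 planted blinks."""
    spec = EEGSpec(n_channels=3, duration=10.0, fs=250.0,
                   sine_components=((10.0, 1.0),), n_blinks=5,
                   noise_sd=0.2, seed=3)
    return make_synthetic_eeg(spec)
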