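import numpy as np
import pytest
from hypothesis import settings

from vmdseiz import SyntheticSpec, extract_features, make_dataset, make_tone_mixture

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

TONE_FREQS = [2.0, 24.0, 88.0]
TONE_AMPS = [1.0, 0.5, 0.25]
TONE_FS = 256.0


@pytest.fixture(scope="session")
def tone_mixture():
    """Noise-free {2, 24, 88} Hz mixture, 4 s at 256 Hz."""
    return make_tone_mixture(TONE_FREQS, TONE_AMPS, TONE_FS, 4.0)


@pytest.fixture(scope="session")
def small_dataset():
    """8-channel dataset with 2 planted channels, 40 epochs per class."""
    spec = SyntheticSpec(
        n_channels=8, informative_channels=(1, 5), n_epochs_per_class=40, seed=11
    )
    epochs, truth = make_dataset(spec)
    return epochs, truth, spec


@pytest.fixture(scope="session")
def small_features(small_dataset):
    epochs, truth, spec = small_dataset
    with np.errstate(all="ignore"):
        fm = extract_features(epochs, spec.fs)
    return fm, truth


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-layout dataset: 8 channels, 5 planted, 100+100 epochs."""
    spec = SyntheticSpec()
    epochs, truth = make_dataset(spec)
    return epochs, truth, spec


@pytest.fixture(scope="session")
def default_features(default_dataset):
    epochs, truth, spec = default_dataset
    fm = extract_features(epochs, spec.fs)
    return fm, truth


@pytest.fixture(scope="session")
def null_features():
    """No informative channels: class-conditional distributions identical."""
    spec = SyntheticSpec(
        informative_channels=(), n_epochs_per_class=50, seed=5
    )
    epochs, _ = make_dataset(spec)
    return extract_features(epochs, spec.fs)
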