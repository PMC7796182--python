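import numpy as np
import pytest
from hypothesis import settings

import weedvision as wv

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_leaf_set():
    """120 + 120 synthetic leaves with labels, shared across tests."""
    images, labels, manifest = wv.make_dataset(120, 120, seed=0)
    return images, labels, manifest


@pytest.fixture(scope="session")
def trained_model(small_leaf_set):
    """A GGCM+RotLBP classifier trained on the shared leaf set."""
    images, labels, _ = small_leaf_set
    model, report = wv.train_leaf_classifier(images, labels,
                                             strategy="GGCM+RotLBP", seed=0)
    return model, report
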