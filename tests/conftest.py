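import numpy as np
import pytest

from glioseg import phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 64x64 phantom shared across tests."""
    return phantom.generate_phantom(7, 64, 64)


@pytest.fixture(scope="session")
def easy_dataset():
    """Ten small, high-contrast phantoms with mild noise for training."""
    images, labels = [], []
    for s in range(10):
        p = phantom.generate_phantom(300 + s, 64, 64)
        ch = np.stack([
            phantom.add_noise(p.channels[c], "gaussian", 10.0, seed=s * 4 + c)
            for c in range(4)
        ])
        images.append(ch)
        labels.append(p.labels)
    return images, labels
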