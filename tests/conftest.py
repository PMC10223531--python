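import numpy as np
import pytest

from veinroi import synthetic as syn


@pytest.fixture(scope="session")
def small_samples():
    """A small mixed-condition sample set shared by read-only tests."""
    return syn.make_samples(12, seed=7, image_size=(96, 96), keep_mask=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
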