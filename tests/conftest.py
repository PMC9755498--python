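import numpy as np
import pytest

from aopnet.synthetic import generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantoms():
    """A handful of small phantoms shared across fast tests."""
    return generate_dataset(8, base_seed=7, patients=4, image_size=(96, 128))


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at the standard 512 x 384 processing size."""
    return generate_dataset(1, base_seed=3, patients=1)[0]
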