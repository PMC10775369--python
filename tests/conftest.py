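import numpy as np
import pytest

from mifpipe.preprocess import preprocess_dataset
from mifpipe.synth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_cycles=4, n_fovs=2, n_channels_per_cycle=3,
                           image_shape=(256, 256), n_cells=60, max_shift=10,
                           seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A small cyclic acquisition with ground truth, shared read-only."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    ds, _ = small_dataset
    return preprocess_dataset(ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
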