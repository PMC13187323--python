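import numpy as np
import pytest

from bccxai import RaterSpec, generate_lesion_dataset, simulate_raters


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-image synthetic cohort shared by read-only tests."""
    return generate_lesion_dataset(40, image_size=32, seed=7)


@pytest.fixture(scope="session")
def vote_tensor(small_dataset):
    specs = [RaterSpec(0.9, 0.9)] * 3
    return simulate_raters(small_dataset.true_labels, specs, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
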