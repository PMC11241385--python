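import numpy as np
import pytest

from neosono import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_dataset():
    """Balanced 10-per-class phantom set shared by the slower tests."""
    return generate_dataset(10, PhantomConfig(), seed=42)
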