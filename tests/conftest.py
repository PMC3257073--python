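import numpy as np
import pytest

from ubisite import encoders, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial synthetic benchmark shared across tests."""
    spec = synthetic.SyntheticSpec(n_proteins=12, seed=7)
    return synthetic.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_encoded(small_dataset):
    return encoders.encode_dataset(
        small_dataset.windows(), small_dataset.provider()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
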