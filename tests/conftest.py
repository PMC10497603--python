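import numpy as np
import pytest

from specband import synthcube


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight VIS-range samples, 5 nm step: fast enough for unit tests."""
    samples, truth = synthcube.generate_dataset(synthcube.tiny_params())
    return samples, truth


@pytest.fixture(scope="session")
def small_samples():
    """24 full-range samples at 5 nm step for pipeline-level tests."""
    samples, truth = synthcube.generate_dataset(synthcube.small_params())
    return samples, truth
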