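import numpy as np
import pytest

from fcmseg import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def blobs():
    """Three well-separated 2-D blobs, 25 points each, labels attached."""
    g = np.random.default_rng(7)
    data = np.concatenate(
        [g.normal(loc=5.0 * k, scale=0.3, size=(25, 2)) for k in range(3)]
    )
    labels = np.repeat(np.arange(3), 25)
    return data, labels


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 default-style phantom used by image/evaluation tests."""
    return generate_phantom(
        PhantomSpec(shape=(64, 64), noise_sigma=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(
        PhantomSpec(shape=(64, 64), noise_sigma=0.0, seed=0)
    )
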