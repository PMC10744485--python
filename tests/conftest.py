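import numpy as np
import pytest

from vert2ct.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def phantom_pair(noiseless_spec):
    """One deterministic noiseless phantom (volume, mask)."""
    return generate_phantom(noiseless_spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
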