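import numpy as np
import pytest

from imsctseg.phantom import PhantomSpec, generate_subject


@pytest.fixture(scope="session")
def mini_spec():
    """Small phantom spec used across tests (divisible by 2**3)."""
    return PhantomSpec(grid_shape=(48, 32, 16), seed=9)


@pytest.fixture(scope="session")
def subject(mini_spec):
    return generate_subject(mini_spec, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
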