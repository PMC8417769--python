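import numpy as np
import pytest

from hypothseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def desk_phantom():
    """One deterministic 32^3 phantom pair shared across tests."""
    return generate_phantom(PhantomConfig.desk(32, seed=1))


@pytest.fixture(scope="session")
def tiny_phantom():
    """A 16^3 phantom pair for tests that iterate many augmentation draws."""
    return generate_phantom(PhantomConfig.desk(16, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
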