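import numpy as np
import pytest

from deepmir.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def tiny_phantom():
    """One small phantom with all object types, shared across tests."""
    cfg = PhantomConfig(shape=(32, 32, 16), n_cmb=3, n_iron=2,
                        n_calcification=2, n_vessels=2, seed=7)
    vol, truth = generate_phantom(cfg)
    return cfg, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
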