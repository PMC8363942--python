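import numpy as np
import pytest

import somamap as sm
from somamap.estimator import desk_train_config, train


@pytest.fixture(scope="session")
def protocol():
    return sm.default_protocol()


@pytest.fixture(scope="session")
def mini_model(protocol):
    """Quick low-capacity network for plumbing and continuity tests."""
    cfg = desk_train_config(seed=7, n_samples=2 ** 13, epochs=120,
                            hidden=(32, 32), batch_size=1024)
    return train(protocol, cfg)


@pytest.fixture(scope="session")
def desk_model(protocol):
    """Desk-scale trained estimator shared by the acceptance checks."""
    return train(protocol, desk_train_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_tissue_params(n, rng):
    return sm.sample_tissue_params(n, rng)
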