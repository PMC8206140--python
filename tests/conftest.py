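import numpy as np
import pytest

from mayleonard import default_params, desk_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """A small, fast population: reduced box, ~150 individuals per species."""
    return desk_params(0.25, capacity=10, init_per_species=150,
                       relax_steps=0, measure_steps=50, seed=7)


@pytest.fixture
def defaults():
    return default_params()
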