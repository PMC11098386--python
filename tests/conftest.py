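import numpy as np
import pytest

from phacksim import Parameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """A fast-to-simulate configuration preserving the default rates."""
    return Parameters(n_researchers=50, n_steps=200, n_replicates=2, base_seed=7)
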