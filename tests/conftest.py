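import numpy as np
import pytest

from latentfc import simulate_fc_stack


@pytest.fixture(scope="session")
def small_stack():
    """300 subjects x 9 states x 45 edges, equal loadings 0.7."""
    stack, truth = simulate_fc_stack(300, 10, 9, loading_spec=0.7, seed=11)
    return stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
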