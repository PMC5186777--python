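import numpy as np
import pytest

from tomnet import ModelParams


@pytest.fixture(scope="session")
def random_quadruples():
    """1000 parameter quadruples drawn uniformly from the unit hypercube."""
    rng = np.random.default_rng(20160)
    return [ModelParams(*row) for row in rng.random((1000, 4))]


@pytest.fixture
def example_params():
    """The worked-example parameter setting used throughout the docs."""
    return ModelParams(pi_B=0.8, pi_V=0.7, delta=0.05, epsilon=0.02)
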