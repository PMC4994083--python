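import numpy as np
import pytest

from resgame import ModelParams, sample_environment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params():
    """A small community for fast dynamics tests."""
    return ModelParams(
        community_size=50,
        num_resources=3,
        num_consumed=2,
        r_max=30.0,
        selection_intensity=1.0,
        mutation_prob=1e-3,
    )


@pytest.fixture
def env3(rng):
    return sample_environment(3, 30.0, rng)
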