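import numpy as np
import pytest

from gtrca.simulate import SyntheticParams, generate_group_ssvep


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_group():
    """A small but realistic synthetic group: 3 subjects, 4 trials, 8 channels."""
    params = SyntheticParams(A=3, K=4, C=2, n=8, fs=100.0, tau_seconds=0.5, seed=7)
    datasets, truth = generate_group_ssvep(params)
    return params, datasets, truth


@pytest.fixture(scope="session")
def desk_group():
    """The default desk-scale study: 5 subjects, 6 trials, 16 channels, 4 conditions."""
    params = SyntheticParams()
    datasets, truth = generate_group_ssvep(params)
    return params, datasets, truth
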