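import numpy as np
import pytest

from dfcstates import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_factor_problem():
    """Planted C = D A + noise at small scale (M=40, T=80, k=3)."""
    return synth.gen_sparse_factor_problem(M=40, T=80, k=3, noise_sd=0.01, seed=7)


@pytest.fixture(scope="session")
def template_maps():
    return synth.gen_map_set(n_templates=10, seed=1)
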