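import numpy as np
import pytest

from behavar import MCMCConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def fast_mcmc():
    return MCMCConfig(n_chains=2, n_warmup=200, n_samples=400, seed=7,
                      compute_diagnostics=False)
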