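import numpy as np
import pytest

import allobayes as ab


@pytest.fixture(scope="session")
def default_trees():
    """A 39-tree synthetic destructive sample (three age cohorts)."""
    return ab.generate_trees(ab.TreeSimConfig(seed=11))


@pytest.fixture(scope="session")
def stem_data(default_trees):
    return ab.to_log_data(default_trees, "stem")


@pytest.fixture
def short_mcmc():
    """Short chain for tests that do not need long-run precision."""
    return ab.McmcConfig(n_iter=4_000, burn_in=1_000, thin=1, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
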