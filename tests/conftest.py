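import dataclasses

import numpy as np
import pytest

import selfthinning as st


@pytest.fixture(scope="session")
def table1_panel():
    return st.generate_table1_like(seed=1)


@pytest.fixture(scope="session")
def thinning_dataset(table1_panel):
    return st.to_log_pairs(st.filter_self_thinning(table1_panel))


@pytest.fixture(scope="session")
def quick_mcmc():
    """Reduced chain settings for tests: 5,000 iterations, 1,000 burn-in, thin 2."""
    return st.MCMCConfig(n_iter=5000, burn_in=1000, thin=2, n_chains=2, seed=42)


@pytest.fixture
def reseeded(quick_mcmc):
    def _with_seed(seed):
        return dataclasses.replace(quick_mcmc, seed=seed)

    return _with_seed


def make_dataset(x, y, groups=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if groups is None:
        groups = np.ones(len(x), dtype=int)
    groups = np.asarray(groups, dtype=int)
    ids = tuple(f"P{i}" for i in sorted(set(groups.tolist())))
    return st.ModelDataset(lnN=x, lnV=y, plot_index=groups, plot_ids=ids)
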