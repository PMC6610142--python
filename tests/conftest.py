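import numpy as np
import pandas as pd
import pytest

from enterokit import SyntheticConfig, generate_cohort, to_relative_abundance
from enterokit.beta import unifrac_matrix


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (51 samples, 15/36)."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_wuf(default_cohort):
    rel = to_relative_abundance(default_cohort.otu_table)
    return unifrac_matrix(default_cohort.tree, rel, weighted=True)


@pytest.fixture(scope="session")
def genus_relabund(default_cohort):
    return to_relative_abundance(default_cohort.otu_table.genus_table())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_correlation(rng, n, n_obs=25):
    """Sample correlation matrix of random Gaussian data."""
    x = rng.normal(size=(n_obs, n))
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2, -1, 1)
    np.fill_diagonal(r, 1.0)
    return r


def toy_table(counts, sample_ids=None, otu_ids=None):
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"s{i}" for i in range(counts.shape[0])]
    otu_ids = otu_ids or [f"o{j}" for j in range(counts.shape[1])]
    from enterokit.io import OtuTable
    return OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))
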