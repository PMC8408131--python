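import numpy as np
import pandas as pd
import pytest

import floramark as fm
from floramark import expression_prep as prep


@pytest.fixture(scope="session")
def small_dataset():
    """Planted-truth dataset small enough for fast unit tests."""
    plan = fm.GenePlan().scaled(800)
    cm, design, truth = fm.generate_expression(gene_plan=plan, seed=42)
    return cm, design, truth.set_index("gene_id")


@pytest.fixture(scope="session")
def small_profile(small_dataset):
    cm, design, _ = small_dataset
    tpm = prep.counts_to_tpm(cm)
    return prep.tissue_means(tpm, design)


@pytest.fixture(scope="session")
def module_dataset():
    """Three planted 50-gene modules anchored to distinct tissues, plus background."""
    plan = fm.GenePlan(
        n_specific_per_tissue=0,
        n_housekeeping=0,
        n_background=600,
        modules=((50, 0), (50, 1), (50, 2)),
    )
    cm, design, truth = fm.generate_expression(gene_plan=plan, seed=3)
    tpm = prep.counts_to_tpm(cm)
    profile = prep.tissue_means(tpm, design)
    keep = prep.filter_for_network(profile)
    mat = np.log2(profile.loc[keep] + 1.0)
    return mat, truth.set_index("gene_id")


def random_symmetric_adjacency(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a
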