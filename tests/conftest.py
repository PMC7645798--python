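import numpy as np
import pandas as pd
import pytest

import mechstrat as ms


@pytest.fixture(scope="session")
def catalog():
    return ms.default_catalog()


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study design for fast unit tests (full SNP panel)."""
    return ms.SyntheticConfig(n_patients_ad=90, n_patients_pd=60, n_validation=80, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ms.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_grouping(catalog, small_cohort):
    return ms.group_snps_by_mechanism(catalog, small_cohort.genotypes.snp_ids)


@pytest.fixture(scope="session")
def small_profile(small_cohort, small_grouping):
    return ms.compute_burden_scores(
        small_cohort.genotypes, small_grouping, ms.EncoderSpec(seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def block_matrix(n_per_block: int, k: int, noise: float, rng, m_per_block: int = 3):
    """Non-negative block-structured matrix with k planted row groups."""
    n, m = n_per_block * k, m_per_block * k
    X = np.full((n, m), 0.1)
    for c in range(k):
        rows = slice(c * n_per_block, (c + 1) * n_per_block)
        cols = slice(c * m_per_block, (c + 1) * m_per_block)
        X[rows, cols] = 1.0
    X += noise * rng.random((n, m))
    labels = np.repeat(np.arange(k), n_per_block)
    return X, labels
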