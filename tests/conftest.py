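import numpy as np
import pytest

import ssrimet as sm


@pytest.fixture(scope="session")
def small_truth():
    """p=10, two planted communities, a handful of edges."""
    return sm.make_precision_matrix(10, n_communities=2, within_density=0.3, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return sm.simulate_cohort(n_subjects=60, ground_truth=small_truth, seed=11)


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    return sm.preprocess_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
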