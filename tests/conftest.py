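import numpy as np
import pytest

from elastica.affinity import build_affinities
from elastica.optimizer import EEParams
from elastica.preprocess import pca_reduce
from elastica.synthetic_data import make_tree


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gaussian():
    """30 x 4 standard-normal points."""
    return np.random.default_rng(7).standard_normal((30, 4))


@pytest.fixture(scope="session")
def small_model(small_gaussian):
    return build_affinities(small_gaussian, perplexity=8.0)


@pytest.fixture(scope="session")
def small_params():
    return EEParams(perplexity=8.0, dim=2, seed=0, max_iter=40)


@pytest.fixture(scope="session")
def tree_pcs():
    """Full-scale branching tree (1,440 x 60) reduced to 7 principal components."""
    ds = make_tree(10, 144, 60, 0.1, seed=1)
    return pca_reduce(ds.data, 7).values
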