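import numpy as np
import pytest

from codres.fixtures import FixtureSpec, golden_tables


@pytest.fixture(scope="session")
def golden():
    return golden_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    return FixtureSpec(seed=7, n_drugs=12, n_tools=3, n_datasets=3,
                       n_genes=40, n_clusters=3, consensus_fraction=0.5)
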