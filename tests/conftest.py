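import numpy as np
import pytest

from ctdx.genome import hg19_genome, toy_genome
from ctdx.simulate import (
    make_index_patient_fixture,
    make_variant_cascade_fixture,
    simulate_index_af_matrix,
)


@pytest.fixture(scope="session")
def toy():
    return toy_genome()


@pytest.fixture(scope="session")
def hg19_small():
    return hg19_genome(n_bins=2_000)


@pytest.fixture(scope="session")
def index_fixture():
    return make_index_patient_fixture(seed=0)


@pytest.fixture(scope="session")
def index_af_matrix(index_fixture):
    _, af = simulate_index_af_matrix(index_fixture, depth=10_000, seed=1)
    return af


@pytest.fixture(scope="session")
def cascade_fixture():
    return make_variant_cascade_fixture(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
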