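import numpy as np
import pytest

from tridimer.contacts import ContactParams
from tridimer.structures import extract_tridimer
from tridimer.synthetic import SyntheticSpec, make_sbm_test_dimer, make_t3_lattice


CA_PARAMS = ContactParams(cutoff=8.0, min_seq_sep=3)  # CA-only native contacts


@pytest.fixture(scope="session")
def lattice():
    """Default synthetic T=3 lattice (180 chains)."""
    return make_t3_lattice(SyntheticSpec())


@pytest.fixture(scope="session")
def tridimer(lattice):
    return extract_tridimer(lattice)


@pytest.fixture(scope="session")
def parallel_dimer():
    return make_sbm_test_dimer("parallel")


@pytest.fixture(scope="session")
def hinge_dimer():
    return make_sbm_test_dimer("hinge")


@pytest.fixture(scope="session")
def parallel_top(parallel_dimer):
    from tridimer.sbm import build_sbm
    return build_sbm(parallel_dimer, CA_PARAMS)


@pytest.fixture(scope="session")
def hinge_top(hinge_dimer):
    from tridimer.sbm import build_sbm
    return build_sbm(hinge_dimer, CA_PARAMS)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
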