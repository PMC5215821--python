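import numpy as np
import pytest

from uca_testbed.models import get_model
from uca_testbed.phylo import parse_newick


@pytest.fixture(scope="session")
def rtrev():
    return get_model("rtREV")


@pytest.fixture(scope="session")
def rtrev_gamma():
    return get_model("rtREV", gamma_shape=0.8, n_categories=4)


@pytest.fixture(scope="session")
def lg_gamma():
    return get_model("LG", gamma_shape=0.8, n_categories=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140812 % 2**16)


@pytest.fixture(scope="session")
def quartet_e():
    return parse_newick("((E1:0.4,E2:0.4):0.2,(E3:0.4,E4:0.4):0.2);")


@pytest.fixture(scope="session")
def quartet_b():
    return parse_newick("((B1:0.4,B2:0.4):0.2,(B3:0.4,B4:0.4):0.2);")
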