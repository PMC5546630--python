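import numpy as np
import pytest

from ca3theta.cells import load_cell_catalog
from ca3theta.synapses import load_pathway_catalog
from ca3theta.network import build_network


@pytest.fixture(scope="session")
def cell_catalog():
    return load_cell_catalog()


@pytest.fixture(scope="session")
def raw_cell_catalog():
    return load_cell_catalog(apply_h_scale=False)


@pytest.fixture(scope="session")
def pathway_catalog():
    return load_pathway_catalog()


@pytest.fixture(scope="session")
def ca3_net():
    """A CA3-only network with all intra-CA3 pathways, fixed seed."""
    return build_network(7, regions=("ca3",))


@pytest.fixture(scope="session")
def ec_ca3_net():
    return build_network(7, regions=("ec", "ca3"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
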