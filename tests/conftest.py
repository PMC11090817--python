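import numpy as np
import pytest

from hgt_ecoscape.synthetic import WorldConfig, simulate_world
from hgt_ecoscape.trees import PhyloTree


@pytest.fixture(scope="session")
def small_world():
    """A small noiseless world: aggregation must recover it exactly."""
    cfg = WorldConfig(
        n_species=50,
        n_samples=250,
        n_gene_families=200,
        n_reconciliations=20,
        support_noise=0.0,
        seed=42,
    )
    return simulate_world(cfg)


@pytest.fixture(scope="session")
def noisy_world():
    """A small world with replicate noise at the default level."""
    cfg = WorldConfig(
        n_species=60,
        n_samples=300,
        n_gene_families=300,
        n_reconciliations=25,
        seed=7,
    )
    return simulate_world(cfg)


@pytest.fixture
def three_leaf_tree():
    return PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
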