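import numpy as np
import pytest

from phyloles.phylo import parse_newick, tree_vcv
from phyloles.simulate import FixtureConfig, simulate_fixture, simulate_yule_tree


@pytest.fixture(scope="session")
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_taxon():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study (34 species, fixed seed)."""
    return simulate_fixture(FixtureConfig())


@pytest.fixture(scope="session")
def balanced_tree_128():
    """A deep Yule tree with 128 tips for recovery simulations."""
    return simulate_yule_tree(128, seed=11, depth=1.0)


@pytest.fixture(scope="session")
def balanced_cov_128(balanced_tree_128):
    return tree_vcv(balanced_tree_128)


def random_yule_trees(n_trees, n_tips, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        yield simulate_yule_tree(
            n_tips, seed=rng, depth=float(rng.uniform(0.5, 2.0))
        )
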