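import numpy as np
import pytest

from aggphylo import (
    Alignment,
    M0Params,
    Tree,
    build_codon_space,
    simulate_alignment,
    simulate_birth_death_tree,
)


@pytest.fixture(scope="session")
def space():
    return build_codon_space()


@pytest.fixture(scope="session")
def equal_pi():
    return np.full(61, 1.0 / 61)


@pytest.fixture(scope="session")
def dirichlet_pi():
    return np.random.default_rng(42).dirichlet(np.ones(61))


@pytest.fixture()
def four_taxon_tree():
    return Tree.from_newick("((a:0.2,b:0.3):0.15,(c:0.1,d:0.25):0.05);")


@pytest.fixture(scope="session")
def small_m0_dataset(equal_pi):
    """A 6-tip, 40-codon alignment simulated under M0 (omega=0.3, kappa=2)."""
    tree = simulate_birth_death_tree(6, target_tree_length=1.5, seed=7)
    params = M0Params(omega=0.3, kappa=2.0, pi=equal_pi)
    aln = simulate_alignment(tree, params, 40, seed=2)
    return aln, tree, params
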