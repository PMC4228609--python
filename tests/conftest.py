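import numpy as np
import pytest
from hypothesis import settings

import litterevo as le
from litterevo.simulate import SimulationConfig, simulate_tree

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — depth 2, one cherry."""
    return le.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def study_tree():
    """A 39-tip pure-birth tree rescaled to 350 Myr depth."""
    return simulate_tree(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree(rng, n_tips: int) -> le.Phylogeny:
    """Random binary tree with uniform branch lengths (not ultrametric)."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i, tax in enumerate(taxa):
        node = dendropy.Node(taxon=tax)
        node.edge.length = float(rng.uniform(0.1, 2.0))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.1, 2.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return le.Phylogeny.from_dendropy(tree)
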