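import numpy as np
import pytest

from inteinflow.io import parse_newick
from inteinflow.simulate import SimulationConfig, run_simulation, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def discordant_quartet():
    return parse_newick("((A:1,C:1):1,(B:1,D:1):1);")


@pytest.fixture(scope="session")
def default_truth():
    """One default-condition simulation shared across tests (12 taxa, 4 alleles)."""
    return run_simulation(SimulationConfig(seed=11))


def random_tree(n_taxa: int, seed: int):
    return simulate_tree(n_taxa, 1.0, seed)


def edge_bipartition_monophyly(tree, focal: frozenset) -> bool:
    """Oracle: some edge's bipartition separates exactly focal from the rest."""
    universe = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            if below[node] == focal or universe - below[node] == focal:
                return True
    return False


def brute_force_parsimony(tree, character: dict) -> int:
    """Oracle: minimum changes over all internal 0/1 labelings (small trees)."""
    import itertools

    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    best = None
    for labels in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, labels))
        for lf in leaves:
            assign[lf] = character[lf.taxon.label]
        changes = sum(
            1
            for n in tree.preorder_node_iter()
            if n.parent_node is not None and assign[n] != assign[n.parent_node]
        )
        best = changes if best is None else min(best, changes)
    return best
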