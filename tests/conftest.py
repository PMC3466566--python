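import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from merphylo import SyntheticConfig, read_newick, simulate_tree

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def balanced4():
    """((A:1,B:1):1,(C:1,D:1):1) - the worked closed-form example tree."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def clade_trait4():
    return np.array([0.0, 0.0, 1.0, 1.0])


@pytest.fixture
def random_chronogram():
    """Factory: seeded ultrametric Yule chronogram with n tips."""

    def make(n_tips=16, seed=0):
        return simulate_tree(SyntheticConfig(n_tips=n_tips, seed=seed))

    return make


def brute_force_patristic(tree, a, b):
    """Independent path-sum oracle: sum branch lengths along the tip-to-tip path."""
    dtree = tree.dendropy_tree

    def path_to_root(label):
        node = next(
            nd for nd in dtree.leaf_node_iter() if nd.taxon.label == label
        )
        path = []
        while node.parent_node is not None:
            path.append((id(node), node.edge.length))
            node = node.parent_node
        return path

    pa, pb = path_to_root(a), path_to_root(b)
    ids_a = {i for i, _ in pa}
    ids_b = {i for i, _ in pb}
    shared = ids_a & ids_b
    return sum(l for i, l in pa if i not in shared) + sum(
        l for i, l in pb if i not in shared
    )
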