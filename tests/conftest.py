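import random
import string

import pytest

from tieclust.fixtures import toy_table1
from tieclust.linkage_enum import enumerate_dendrograms, euclidean_matrix
from tieclust.trees import Dendrogram, Node


def random_tree(labels, rng: random.Random) -> Dendrogram:
    """Random binary leaf-labeled tree by uniform random pair merging."""
    nodes = [Node.leaf(l) for l in labels]
    while len(nodes) > 1:
        i, j = rng.sample(range(len(nodes)), 2)
        merged = Node.join(nodes[i], nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return Dendrogram(nodes[0])


def random_labels(rng: random.Random, n_min=2, n_max=8):
    n = rng.randint(n_min, n_max)
    return rng.sample(string.ascii_lowercase, n)


@pytest.fixture(scope="session")
def toy_trees():
    """The six dendrograms of the planted-ties toy layout."""
    result = enumerate_dendrograms(euclidean_matrix(toy_table1()))
    assert not result.capped
    return result.trees
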