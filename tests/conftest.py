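import numpy as np
import pytest

from hotrecon.tree import Node, PhyloTree, parse_newick


def random_binary_tree(labels, rng) -> PhyloTree:
    """Uniform-ish random rooted binary tree by random cherry joining."""
    nodes = [Node(l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(children=[a, b]))
    return PhyloTree(nodes[0]).canonicalize()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def quartet():
    return parse_newick("((A:1,B:1)95:2,(C:1,D:1)100:2);")


@pytest.fixture
def caterpillar():
    return parse_newick("((((A,B)90,C)80,D)70,E);")
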