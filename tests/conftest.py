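import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from treeot.tree import LineageTree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tree(edges, times, root):
    """Helper: build a LineageTree from (parent, child) pairs and a time map."""
    g = nx.DiGraph()
    for v, t in times.items():
        g.add_node(v, time=float(t))
    g.add_edges_from(edges)
    return LineageTree(g, root)


@pytest.fixture
def cherry_tree():
    """Root dividing at 0.5 into two leaves sampled at 1.0."""
    return make_tree([("r", "a"), ("r", "b")],
                     {"r": 0.5, "a": 1.0, "b": 1.0}, "r")


@pytest.fixture
def five_leaf_tree():
    edges = [("r", "u"), ("r", "v"), ("u", "a"), ("u", "b"),
             ("v", "w"), ("v", "c"), ("w", "d"), ("w", "e")]
    times = {"r": 0.0, "u": 0.3, "v": 0.45, "w": 0.7,
             "a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0, "e": 1.0}
    return make_tree(edges, times, "r")
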