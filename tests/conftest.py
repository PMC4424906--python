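import networkx as nx
import numpy as np
import pytest

from tsppi import AlignmentParameters, TSPPINetwork


def make_network(name, nodes, edges, condition="cond"):
    """TS-PPI network from {node: weight} and [(a, b, weight)]."""
    graph = nx.Graph()
    for node, weight in nodes.items():
        graph.add_node(node, weight=float(weight))
    for a, b, w in edges:
        graph.add_edge(a, b, weight=float(w), label=condition)
    return TSPPINetwork(name=name, conditions=(condition,), graph=graph)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_params():
    """Small search effort for unit tests of the full aligner."""
    return AlignmentParameters(attempts=8, refine_iterations=3, seed=7)


@pytest.fixture
def planted_pair():
    """Two identical 6-node networks with a divergent 3-node triangle.

    Nodes A, B, C form a triangle whose weights differ four-fold between
    the networks; background nodes X, Y, Z keep identical weights.
    """
    edges = [("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.7),
             ("C", "X", 0.5), ("X", "Y", 0.5), ("Y", "Z", 0.5)]
    net1 = make_network("net1", {"A": 16, "B": 16, "C": 16,
                                 "X": 5, "Y": 5, "Z": 5}, edges)
    net2 = make_network("net2", {"A": 4, "B": 4, "C": 4,
                                 "X": 5, "Y": 5, "Z": 5}, edges)
    return net1, net2
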