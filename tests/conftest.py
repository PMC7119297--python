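import itertools

import pandas as pd
import pytest

from scnrank.datatypes import ExpressionMatrix, GeneList
from scnrank.network import IntegratedNetwork


@pytest.fixture
def small_expression():
    """3 genes x 4 samples (2 tumor, 2 normal), log2 scale."""
    values = pd.DataFrame(
        [[5.0, 6.0, 1.0, 2.0],
         [2.0, 2.5, 2.1, 2.4],
         [8.0, 7.5, 8.1, 7.9]],
        index=["GA", "GB", "GC"], columns=["t1", "t2", "n1", "n2"])
    labels = {"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"}
    return ExpressionMatrix(values=values, group_labels=labels)


@pytest.fixture
def three_node_cellline_net():
    """The worked 3-node cluster: edges x-a 0.5, a-b -0.8, x-b 0.1;
    essentialities W_x=-1, W_a=-1, W_b=-2."""
    return IntegratedNetwork(
        nodes=["x", "a", "b"],
        node_weight={"x": -1.0, "a": -1.0, "b": -2.0},
        edge_weight={("a", "x"): 0.5, ("a", "b"): -0.8, ("b", "x"): 0.1},
        context="cellline")


@pytest.fixture
def targets_ab():
    return GeneList(genes=["x", "a"])


def brute_force_best_products(nodes, edge_weight, source):
    """Independent oracle: exhaustive simple-path enumeration.

    Returns {node: (best signed product, magnitude)} over all simple paths
    from source, maximising |product|; zero-weight edges are untraversable.
    """
    adj = {n: {} for n in nodes}
    for (a, b), w in edge_weight.items():
        if w != 0.0 and a in adj and b in adj:
            adj[a][b] = w
            adj[b][a] = w
    best = {source: (1.0, 1.0)}

    def walk(node, visited, product):
        for nxt, w in adj[node].items():
            if nxt in visited:
                continue
            p = product * w
            cur = best.get(nxt)
            if cur is None or abs(p) > cur[1]:
                best[nxt] = (p, abs(p))
            walk(nxt, visited | {nxt}, p)

    walk(source, {source}, 1.0)
    return best


def random_connected_graph(rng, max_nodes=8):
    """Random connected graph with weights in [-1, 1] \\ {0}."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = {}
    for i in range(1, n):  # random tree keeps it connected
        j = int(rng.integers(0, i))
        a, b = min(nodes[i], nodes[j]), max(nodes[i], nodes[j])
        edges[(a, b)] = _rand_weight(rng)
    for i, j in itertools.combinations(range(n), 2):
        a, b = min(nodes[i], nodes[j]), max(nodes[i], nodes[j])
        if (a, b) not in edges and rng.random() < 0.4:
            edges[(a, b)] = _rand_weight(rng)
    return nodes, edges


def _rand_weight(rng):
    w = 0.0
    while w == 0.0:
        w = float(rng.uniform(-1.0, 1.0))
    return w
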