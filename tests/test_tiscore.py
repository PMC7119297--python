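import numpy as np
import pytest

from scnrank.datatypes import GeneList
from scnrank.network import IntegratedNetwork
from scnrank.spectral import ClusterAssignment
from scnrank.tiscore import (max_correlation_paths, rank_targets,
                             target_influence)
from .conftest import brute_force_best_products, random_connected_graph


def make_net(nodes, edge_weight, node_weight=None):
    nw = node_weight or {n: -1.0 for n in nodes}
    ew = {(min(a, b), max(a, b)): w for (a, b), w in edge_weight.items()}
    return IntegratedNetwork(nodes=list(nodes), node_weight=nw,
                             edge_weight=ew, context="cellline")


class TestMaxCorrelationPaths:
    def test_worked_three_node_example(self, three_node_cellline_net):
        net = three_node_cellline_net
        res = {p.target_node: p for p in
               max_correlation_paths(net, {"x", "a", "b"}, "x")}
        assert res["x"].product == 1.0 and res["x"].path == ["x"]
        # direct 0.5 beats 0.1 * -0.8 = -0.08
        assert res["a"].product == pytest.approx(0.5)
        assert res["a"].path == ["x", "a"]
        # via a: 0.5 * -0.8 = -0.4 beats direct 0.1
        assert res["b"].product == pytest.approx(-0.4)
        assert res["b"].path == ["x", "a", "b"]

    def test_unit_weight_chain(self):
        net = make_net(["x", "a", "b"], {("x", "a"): 1.0, ("a", "b"): 1.0})
        res = {p.target_node: p.product for p in
               max_correlation_paths(net, {"x", "a", "b"}, "x")}
        assert res == {"x": 1.0, "a": 1.0, "b": 1.0}

    def test_unreachable_node_omitted(self):
        net = make_net(["x", "a", "z"], {("x", "a"): 0.5})
        reached = {p.target_node for p in
                   max_correlation_paths(net, {"x", "a", "z"}, "x")}
        assert reached == {"x", "a"}

    def test_zero_weight_edge_not_traversable(self):
        net = make_net(["x", "a"], {("x", "a"): 0.0})
        reached = {p.target_node for p in
                   max_correlation_paths(net, {"x", "a"}, "x")}
        assert reached == {"x"}

    def test_search_confined_to_cluster(self):
        # the only route inside the cluster is direct; the better outside
        # detour through z must be ignored
        net = make_net(["x", "a", "z"],
                       {("x", "a"): 0.2, ("x", "z"): 0.9, ("z", "a"): 0.9})
        res = {p.target_node: p for p in
               max_correlation_paths(net, {"x", "a"}, "x")}
        assert res["a"].product == pytest.approx(0.2)

    def test_source_outside_cluster_rejected(self, three_node_cellline_net):
        with pytest.raises(ValueError, match="not in cluster"):
            max_correlation_paths(three_node_cellline_net, {"a", "b"}, "x")

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            nodes, edges = random_connected_graph(rng)
            net = make_net(nodes, edges)
            source = nodes[int(rng.integers(len(nodes)))]
            oracle = brute_force_best_products(nodes, net.edge_weight, source)
            got = {p.target_node: p for p in
                   max_correlation_paths(net, set(nodes), source)}
            assert set(got) == set(oracle)
            for node, (best_prod, best_mag) in oracle.items():
                assert got[node].magnitude == pytest.approx(best_mag, abs=1e-12)
                assert np.sign(got[node].product) == np.sign(best_prod)

    def test_adding_edge_cannot_decrease_magnitudes(self):
        rng = np.random.default_rng(5)
        nodes, edges = random_connected_graph(rng, max_nodes=6)
        net = make_net(nodes, edges)
        base = {p.target_node: p.magnitude for p in
                max_correlation_paths(net, set(nodes), nodes[0])}
        # add one new strong edge
        missing = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                   if (min(a, b), max(a, b)) not in net.edge_weight]
        if missing:
            ew = dict(net.edge_weight)
            ew[missing[0]] = 0.95
            net2 = make_net(nodes, ew)
            after = {p.target_node: p.magnitude for p in
                     max_correlation_paths(net2, set(nodes), nodes[0])}
            for node, mag in base.items():
                assert after[node] >= mag - 1e-12


class TestTargetInfluence:
    def test_worked_example_ti(self, three_node_cellline_net):
        score = target_influence(three_node_cellline_net, {"x", "a", "b"}, "x")
        # hand sum: (-1)(1) + (-1)(0.5) + (-2)(-0.4) = -0.7
        assert score.TI == pytest.approx(-0.7, abs=1e-12)
        assert score.abs_TI == pytest.approx(0.7, abs=1e-12)
        assert score.reachable_count == 3

    def test_singleton_cluster_self_term(self):
        net = make_net(["x"], {}, node_weight={"x": -2.0})
        score = target_influence(net, {"x"}, "x")
        assert score.TI == pytest.approx(-2.0)

    def test_zero_essentiality_annihilates(self, three_node_cellline_net):
        net = three_node_cellline_net
        zero = IntegratedNetwork(nodes=net.nodes,
                                 node_weight={n: 0.0 for n in net.nodes},
                                 edge_weight=dict(net.edge_weight),
                                 context="cellline")
        assert target_influence(zero, set(net.nodes), "x").TI == 0.0

    def test_linearity_in_node_weights(self, three_node_cellline_net):
        net = three_node_cellline_net
        scaled = IntegratedNetwork(
            nodes=net.nodes,
            node_weight={n: 3.0 * w for n, w in net.node_weight.items()},
            edge_weight=dict(net.edge_weight), context="cellline")
        t1 = target_influence(net, set(net.nodes), "x").TI
        t2 = target_influence(scaled, set(net.nodes), "x").TI
        assert t2 == pytest.approx(3.0 * t1)

    def test_cluster_locality(self):
        # edits outside the cluster's induced subgraph leave TI unchanged
        nodes = ["x", "a", "u", "v"]
        base = {("x", "a"): 0.5, ("u", "v"): 0.9}
        nw = {"x": -1.0, "a": -1.5, "u": -9.0, "v": -9.0}
        net1 = make_net(nodes, base, node_weight=nw)
        edited = dict(base)
        edited[("a", "u")] = 0.99  # edge leaving the cluster
        nw2 = dict(nw)
        nw2["u"] = 5.0
        net2 = make_net(nodes, edited, node_weight=nw2)
        cluster = {"x", "a"}
        t1 = target_influence(net1, cluster, "x").TI
        t2 = target_influence(net2, cluster, "x").TI
        assert t1 == pytest.approx(t2)


def assignment_for(netnodes, mapping):
    k = max(mapping.values()) + 1
    return ClusterAssignment(assignment=mapping, K=k,
                             embedding=np.zeros((len(netnodes), 1)),
                             eigenvalues=np.zeros(1))


class TestRankTargets:
    def _two_cluster_net(self):
        nodes = ["x", "a", "y", "b"]
        ew = {("x", "a"): 0.9, ("y", "b"): 0.5}
        nw = {"x": -3.0, "a": -1.0, "y": -1.0, "b": -0.5}
        net = make_net(nodes, ew, node_weight=nw)
        mapping = {"x": 0, "a": 0, "y": 1, "b": 1}
        return net, assignment_for(nodes, mapping)

    def test_global_ranking_by_abs_ti(self):
        net, assign = self._two_cluster_net()
        table = rank_targets(net, assign, GeneList(genes=["x", "y"]))
        frame = table.to_frame()
        assert list(frame["gene"]) == ["x", "y"]
        assert list(frame["rank"]) == [1, 2]
        assert frame["abs_TI"].is_monotonic_decreasing

    def test_cluster_representative_is_max_abs_ti(self):
        net, assign = self._two_cluster_net()
        table = rank_targets(net, assign, GeneList(genes=["x", "a", "y"]))
        assert table.representatives[0] == "x"

    def test_target_missing_from_network_skipped(self, caplog):
        net, assign = self._two_cluster_net()
        with caplog.at_level("INFO"):
            table = rank_targets(net, assign,
                                 GeneList(genes=["x", "NOT_THERE"]))
        assert [s.gene for s in table.scores] == ["x"]
        assert any("absent from the network" in r.message for r in caplog.records)

    def test_tie_broken_lexicographically(self):
        nodes = ["a", "b", "c", "d"]
        ew = {("a", "b"): 0.5, ("c", "d"): 0.5}
        nw = {n: -1.0 for n in nodes}
        net = make_net(nodes, ew, node_weight=nw)
        assign = assignment_for(nodes, {"a": 0, "b": 0, "c": 1, "d": 1})
        table = rank_targets(net, assign, GeneList(genes=["c", "a"]))
        assert [s.gene for s in table.scores] == ["a", "c"]
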