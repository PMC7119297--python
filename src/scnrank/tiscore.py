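"""Target Influence scoring on the cell-line network.

A drug target's influence is confined to its cluster. For every other
gene in the cluster the "most correlated path" is the one maximising the
absolute product of edge correlations; since |r| <= 1, Dijkstra on edge
costs -log|r| (non-negative) finds it, and the signed product along the
chosen path records whether the association is positive or negative.
The Target Influence score is

    TI = sum over reachable cluster genes k of
         essentiality(k) * signed max-magnitude path product(target -> k)

with the target itself contributing essentiality(target) * 1 (empty
path). Targets are ranked by |TI| descending (strong targets have large
negative essentiality sums, so magnitude is the ranking key); the signed
TI is always reported alongside. Zero-weight edges are non-traversable.

A "reciprocal" path mode (Dijkstra on 1/|r| costs) is kept for
comparison; it favours short high-|r| first hops but does not optimise
the path product.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .datatypes import GeneList
from .network import IntegratedNetwork
from .spectral import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass
class PathResult:
    source: str
    target_node: str
    product: float    # signed product of edge correlations along the path
    magnitude: float  # |product|
    path: list[str]   # node sequence from source to target_node


@dataclass
class TargetScore:
    gene: str
    cluster_id: int
    TI: float
    abs_TI: float
    reachable_count: int
    rank: int | None = None


@dataclass
class RankedTargetTable:
    scores: list[TargetScore]                 # sorted by abs_TI descending
    representatives: dict[int, str]           # cluster_id -> top target

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.gene, s.cluster_id, s.TI, s.abs_TI, s.rank, s.reachable_count)
             for s in self.scores],
            columns=["gene", "cluster_id", "TI", "abs_TI", "rank",
                     "reachable_count"])


def _cluster_graph(net: IntegratedNetwork, cluster_nodes: set[str],
                   mode: str = "logprod") -> nx.Graph:
    """Induced subgraph on the cluster with path-search edge costs attached."""
    g = nx.Graph()
    g.add_nodes_from(n for n in net.nodes if n in cluster_nodes)
    for (a, b), r in net.edge_weight.items():
        if a in cluster_nodes and b in cluster_nodes and r != 0.0:
            if mode == "logprod":
                cost = -math.log(abs(r))
            elif mode == "reciprocal":
                cost = 1.0 / abs(r)
            else:
                raise ValueError(f"unknown path mode {mode!r}")
            g.add_edge(a, b, r=r, cost=cost)
    return g


def max_correlation_paths(net: IntegratedNetwork, cluster_nodes: set[str],
                          source: str, mode: str = "logprod"
                          ) -> list[PathResult]:
    """Most-correlated paths from ``source`` to every reachable cluster gene.

    Returns one PathResult per reachable node (the source itself included,
    with an empty path and product 1); unreachable nodes are omitted.
    """
    if source not in cluster_nodes:
        raise ValueError(f"source {source!r} not in cluster")
    g = _cluster_graph(net, cluster_nodes, mode=mode)
    if source not in g:
        # isolated source: only the self path exists
        return [PathResult(source, source, 1.0, 1.0, [source])]
    _, paths = nx.single_source_dijkstra(g, source, weight="cost")
    out: list[PathResult] = []
    for node, path in paths.items():
        prod = 1.0
        for u, v in zip(path, path[1:]):
            prod *= g[u][v]["r"]
        out.append(PathResult(source=source, target_node=node, product=prod,
                              magnitude=abs(prod), path=path))
    return out


def target_influence(net: IntegratedNetwork, cluster_nodes: set[str],
                     target: str, cluster_id: int = -1,
                     mode: str = "logprod") -> TargetScore:
    """TI of one target within its cluster on the cell-line network."""
    paths = max_correlation_paths(net, cluster_nodes, target, mode=mode)
    ti = 0.0
    for p in paths:
        ti += net.node_weight[p.target_node] * p.product
    return TargetScore(gene=target, cluster_id=cluster_id, TI=ti,
                       abs_TI=abs(ti), reachable_count=len(paths))


def rank_targets(net_cellline: IntegratedNetwork,
                 assignment: ClusterAssignment,
                 targets: GeneList,
                 mode: str = "logprod") -> RankedTargetTable:
    """Score every network-mapped target in its own cluster and rank globally.

    Ranking is by |TI| descending with lexicographic gene-id tie-break.
    Per-cluster representatives are the top-|TI| target of each cluster.
    Targets absent from the network are logged and skipped.
    """
    node_set = set(net_cellline.nodes)
    mapped = [t for t in targets.genes if t in node_set and t in assignment.assignment]
    skipped = [t for t in targets.genes if t not in node_set]
    if skipped:
        logger.info("rank_targets: %d/%d targets absent from the network, skipped",
                    len(skipped), len(targets.genes))
    members: dict[int, set[str]] = {}
    for g, c in assignment.assignment.items():
        members.setdefault(c, set()).add(g)
    scores: list[TargetScore] = []
    for t in mapped:
        c = assignment.assignment[t]
        scores.append(target_influence(net_cellline, members[c], t,
                                       cluster_id=c, mode=mode))
    scores.sort(key=lambda s: (-s.abs_TI, s.gene))
    for i, s in enumerate(scores):
        s.rank = i + 1
    representatives: dict[int, str] = {}
    for s in scores:  # first hit per cluster is its maximal-|TI| target
        representatives.setdefault(s.cluster_id, s.gene)
    return RankedTargetTable(scores=scores, representatives=representatives)
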