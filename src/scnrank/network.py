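"""Construction of the paired tissue and cell-line integrated networks.

Both networks share one skeleton: the PPI edges restricted to the genes
selected as over-expressed in tumor tissue. Edge weights are Pearson
correlations computed in the matching expression context (tumor tissue
columns for the tissue network, cell-line columns for the cell-line
network); node weights are log fold changes (tissue) or CRISPR
essentiality values (cell line). Correlations are computed only for the
PPI pairs, never for the full dense gene × gene matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PPIEdgeList
from .diffexpr import DiffExprResult
from .preprocess import EssentialityTable

logger = logging.getLogger(__name__)


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class IntegratedNetwork:
    """PPI-skeleton graph with context-specific node and edge weights."""

    nodes: list[str]
    node_weight: dict[str, float]
    edge_weight: dict[tuple[str, str], float]  # canonical-order keys, |w| <= 1
    context: str  # "tissue" | "cellline"

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate nodes")
        if self.context not in ("tissue", "cellline"):
            raise ValueError(f"invalid context {self.context!r}")
        self.edge_weight = {_canon(a, b): w for (a, b), w in self.edge_weight.items()}
        for (a, b), w in self.edge_weight.items():
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge endpoint not a node: {(a, b)}")
            if abs(w) > 1 + 1e-9:
                raise ValueError(f"edge weight out of [-1, 1]: {(a, b)} -> {w}")
        missing = node_set - set(self.node_weight)
        if missing:
            raise ValueError(f"nodes without weight: {sorted(missing)[:5]}")
        if self.context == "tissue":
            bad = [g for g in self.nodes if self.node_weight[g] <= 0]
            if bad:
                raise ValueError(
                    f"tissue network requires positive node weights; offending: {bad[:5]}")

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.edge_weight)

    def degree(self, gene: str) -> int:
        return sum(1 for a, b in self.edge_weight if gene in (a, b))

    def neighbors(self, gene: str) -> list[str]:
        out = []
        for a, b in self.edge_weight:
            if a == gene:
                out.append(b)
            elif b == gene:
                out.append(a)
        return out


def pearson_edges(m: ExpressionMatrix, genes: list[str],
                  candidate_edges: set[tuple[str, str]],
                  sample_ids: list[str] | None = None
                  ) -> dict[tuple[str, str], float]:
    """Pearson r for each candidate gene pair over the given samples.

    Pairs where either gene has zero variance get weight 0 (logged).
    Only the candidate pairs are evaluated.
    """
    cols = sample_ids if sample_ids is not None else m.sample_ids
    if len(cols) < 3:
        raise ValueError("need >= 3 samples for correlation")
    sub = m.values.loc[genes, cols].to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(genes)}
    centered = sub - sub.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    weights: dict[tuple[str, str], float] = {}
    n_flat = 0
    for a, b in candidate_edges:
        ia, ib = idx[a], idx[b]
        if norms[ia] == 0.0 or norms[ib] == 0.0:
            n_flat += 1
            weights[_canon(a, b)] = 0.0
            continue
        r = float(centered[ia] @ centered[ib] / (norms[ia] * norms[ib]))
        weights[_canon(a, b)] = float(np.clip(r, -1.0, 1.0))
    if n_flat:
        logger.warning("pearson_edges: %d pairs with a zero-variance gene set to r=0",
                       n_flat)
    return weights


def build_tissue_network(m_tissue: ExpressionMatrix,
                         diff: list[DiffExprResult],
                         ppi: PPIEdgeList) -> IntegratedNetwork:
    """Intersect the over-expressed gene set with the PPI network.

    Nodes are selected genes present in the PPI; edges are the PPI edges
    between them, weighted by Pearson r over tumor tissue samples; node
    weights are the log fold changes. Isolated nodes are retained.
    """
    if not diff:
        raise ValueError("no differential-expression results supplied")
    selected = {r.gene_id: r for r in diff}
    ppi_nodes = ppi.nodes
    nodes = sorted(g for g in selected if g in ppi_nodes)
    if not nodes:
        raise ValueError("no overlap between selection and PPI")
    n_lost = len(selected) - len(nodes)
    logger.info("build_tissue_network: %d selected genes -> %d after PPI overlap "
                "(%d not in PPI)", len(selected), len(nodes), n_lost)
    node_set = set(nodes)
    cand = {e for e in ppi.edges if e[0] in node_set and e[1] in node_set}
    tumor_cols = m_tissue.samples_in_group("tumor")
    ew = pearson_edges(m_tissue, nodes, cand, sample_ids=tumor_cols)
    covered = {g for e in cand for g in e}
    n_isolated = len(node_set - covered)
    if n_isolated:
        logger.info("build_tissue_network: %d isolated nodes retained", n_isolated)
    nw = {g: selected[g].log_fc for g in nodes}
    return IntegratedNetwork(nodes=nodes, node_weight=nw, edge_weight=ew,
                             context="tissue")


def build_cellline_network(m_cellline: ExpressionMatrix,
                           tissue_net: IntegratedNetwork,
                           ess: EssentialityTable) -> IntegratedNetwork:
    """Re-weight the tissue skeleton with cell-line correlations and essentiality.

    The node and edge sets are copied verbatim from the tissue network;
    edge weights are recomputed from cell-line expression columns and node
    weights come from the essentiality table (0 with a warning for genes
    never screened).
    """
    nodes = list(tissue_net.nodes)
    missing_expr = [g for g in nodes if g not in m_cellline.values.index]
    if missing_expr:
        raise ValueError(
            f"genes missing from cell-line expression: {missing_expr[:5]}")
    cl_cols = m_cellline.samples_in_group("cellline")
    ew = pearson_edges(m_cellline, nodes, tissue_net.edges, sample_ids=cl_cols)
    nw: dict[str, float] = {}
    n_missing = 0
    for g in nodes:
        if g in ess.essentiality:
            nw[g] = float(ess.essentiality[g])
        else:
            nw[g] = 0.0
            n_missing += 1
    if n_missing:
        logger.warning("build_cellline_network: %d genes without essentiality "
                       "kept with node weight 0", n_missing)
    return IntegratedNetwork(nodes=nodes, node_weight=nw, edge_weight=ew,
                             context="cellline")


def network_to_frames(net: IntegratedNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge-list and node-weight DataFrames for TSV output."""
    edges = pd.DataFrame(
        [(a, b, w) for (a, b), w in sorted(net.edge_weight.items())],
        columns=["gene_a", "gene_b", "r"])
    nodes = pd.DataFrame(
        [(g, net.node_weight[g]) for g in net.nodes],
        columns=["gene", "weight"])
    return edges, nodes


def network_from_frames(edges: pd.DataFrame, nodes: pd.DataFrame,
                        context: str) -> IntegratedNetwork:
    ew = {_canon(a, b): float(w) for a, b, w in
          edges[["gene_a", "gene_b", "r"]].itertuples(index=False)}
    nw = {g: float(w) for g, w in nodes[["gene", "weight"]].itertuples(index=False)}
    return IntegratedNetwork(nodes=list(nodes["gene"]), node_weight=nw,
                             edge_weight=ew, context=context)
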