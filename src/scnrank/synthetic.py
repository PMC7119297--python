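"""Synthetic tumor/normal/cell-line study generator with known ground truth.

Expression follows a one-factor-per-block Gaussian model: within a block,
gene values share a per-sample latent factor with loading chosen so the
expected pairwise correlation is ``intra_block_r`` (r = loading^2 /
(loading^2 + 1) with unit noise variance). Block genes are shifted by
``effect_size`` log2 units in tumor and cell-line samples but not in
normal samples, so they are the true over-expressed set. The PPI skeleton
contains every within-block pair at high confidence plus Bernoulli
cross-block noise edges. Gene essentiality is strongly negative for one
planted hub per block and mildly negative background noise elsewhere;
sgRNA fold changes scatter around the gene value. All randomness derives
from the single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneList, PPIEdgeList, ProbeMatrix, SgRNATable

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Study-condition knobs for the generator (defaults = desk scale)."""

    n_genes: int = 200
    block_sizes: tuple[int, ...] = (20, 20, 20, 20)
    n_tumor: int = 40
    n_normal: int = 40
    n_cellline: int = 40
    effect_size: float = 1.0          # mean log2 tumor shift of block genes
    intra_block_r: float = 0.7        # target within-block correlation
    expression_sd: float = 0.5        # within-gene, within-group sd (log2 units)
    inter_block_edge_prob: float = 0.05
    hub_essentiality: float = -2.0    # planted hub knockout fold change
    essentiality_mean: float = -0.2   # background essentiality
    essentiality_sd: float = 0.3
    sgrna_noise_sd: float = 0.2
    sgrnas_per_gene: int = 4
    n_crispr_celllines: int = 5
    missing_frac: float = 0.05
    baseline: float = 7.0             # log2-scale baseline expression
    decoy_targets_per_block: int = 3  # non-hub genes added to the target list
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    def validate(self) -> None:
        if sum(self.block_sizes) > self.n_genes:
            raise ValueError("block sizes exceed gene count")
        if any(b < 2 for b in self.block_sizes):
            raise ValueError("blocks need at least 2 genes")
        for p, name in ((self.inter_block_edge_prob, "inter_block_edge_prob"),
                        (self.missing_frac, "missing_frac")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.intra_block_r < 1.0:
            raise ValueError("intra_block_r must be in [0, 1)")


@dataclass
class GroundTruth:
    block_of_gene: dict[str, int]        # block genes only
    overexpressed: set[str]              # the planted true positives
    hub_of_block: dict[int, str]
    expected_hub_order: list[str]        # hubs by |essentiality| descending
    essentiality: dict[str, float]


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate(spec: SyntheticSpec
             ) -> tuple[dict[str, ProbeMatrix], PPIEdgeList, SgRNATable,
                        GeneList, GroundTruth]:
    """Generate all pipeline inputs plus the ground truth.

    Returns ({"tumor_normal": tissue ProbeMatrix, "cellline": cell-line
    ProbeMatrix}, PPIEdgeList, SgRNATable, target GeneList, GroundTruth).
    Probe ids are the gene names with a ``P_`` prefix and a one-to-one
    probe→gene map, so the preprocessing path is exercised end to end.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    n_block_genes = sum(spec.block_sizes)
    block_of_gene: dict[str, int] = {}
    start = 0
    blocks: list[list[str]] = []
    for b, size in enumerate(spec.block_sizes):
        members = genes[start:start + size]
        blocks.append(members)
        for g in members:
            block_of_gene[g] = b
        start += size
    background = genes[n_block_genes:]

    loading = float(np.sqrt(spec.intra_block_r / (1.0 - spec.intra_block_r)))
    # rescale so every gene has within-group sd = expression_sd while the
    # factor-model correlation r = loading^2 / (loading^2 + 1) is preserved
    scale = spec.expression_sd / float(np.sqrt(loading ** 2 + 1.0))
    gene_row = {g: i for i, g in enumerate(genes)}

    def expr_block(n_samples: int, shifted: bool) -> np.ndarray:
        """n_genes x n_samples matrix for one context."""
        x = rng.normal(0.0, 1.0, size=(spec.n_genes, n_samples))
        x *= spec.expression_sd  # background genes: iid noise at the target sd
        block_rows = [gene_row[g] for g in block_of_gene]
        for members in blocks:
            factor = rng.normal(0.0, 1.0, size=n_samples)
            rows = [gene_row[g] for g in members]
            noise = rng.normal(0.0, 1.0, size=(len(rows), n_samples))
            x[rows, :] = scale * (loading * factor[None, :] + noise)
        x += spec.baseline
        if shifted:
            x[block_rows, :] += spec.effect_size
        return x

    tumor = expr_block(spec.n_tumor, shifted=True)
    normal = expr_block(spec.n_normal, shifted=False)
    cellline = expr_block(spec.n_cellline, shifted=True)

    def mask(x: np.ndarray) -> np.ndarray:
        if spec.missing_frac == 0.0:
            return x
        m = rng.random(x.shape) < spec.missing_frac
        # keep at least one observed value per row so imputation is possible
        full_rows = m.all(axis=1)
        if full_rows.any():
            m[full_rows, 0] = False
        out = x.copy()
        out[m] = np.nan
        return out

    probe_ids = [f"P_{g}" for g in genes]
    probe_map = dict(zip(probe_ids, genes))
    tissue_samples = ([f"T{i:03d}" for i in range(spec.n_tumor)]
                      + [f"N{i:03d}" for i in range(spec.n_normal)])
    tissue_labels = {s: ("tumor" if s.startswith("T") else "normal")
                     for s in tissue_samples}
    tissue_values = pd.DataFrame(mask(np.hstack([tumor, normal])),
                                 index=probe_ids, columns=tissue_samples)
    cl_samples = [f"C{i:03d}" for i in range(spec.n_cellline)]
    cl_values = pd.DataFrame(mask(cellline), index=probe_ids, columns=cl_samples)
    matrices = {
        "tumor_normal": ProbeMatrix(values=tissue_values, group_labels=tissue_labels,
                                    probe_to_gene=dict(probe_map)),
        "cellline": ProbeMatrix(values=cl_values,
                                group_labels={s: "cellline" for s in cl_samples},
                                probe_to_gene=dict(probe_map)),
    }

    # PPI: complete within blocks, Bernoulli noise across all other pairs
    scores: dict[tuple[str, str], int] = {}
    for members in blocks:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = sorted((members[i], members[j]))
                scores[(a, b)] = 900
    if spec.inter_block_edge_prob > 0:
        for i in range(spec.n_genes):
            for j in range(i + 1, spec.n_genes):
                a, b = genes[i], genes[j]
                if (a, b) in scores:
                    continue
                if rng.random() < spec.inter_block_edge_prob:
                    scores[(a, b)] = 400
    ppi = PPIEdgeList(scores=scores)

    # essentiality: planted hubs strongly negative, background mildly noisy
    hub_of_block: dict[int, str] = {}
    essentiality: dict[str, float] = {}
    for g in genes:
        essentiality[g] = float(rng.normal(spec.essentiality_mean,
                                           spec.essentiality_sd))
    for b, members in enumerate(blocks):
        hub = members[0]
        hub_of_block[b] = hub
        # small jitter keeps hub magnitudes distinct across blocks
        essentiality[hub] = spec.hub_essentiality + float(rng.normal(0.0, 0.05))

    records = []
    for g in genes:
        for cl in range(spec.n_crispr_celllines):
            for s in range(spec.sgrnas_per_gene):
                fc = essentiality[g] + float(rng.normal(0.0, spec.sgrna_noise_sd))
                records.append((f"{g}_sg{s}", g, f"CL{cl}", fc))
    sgrna = SgRNATable(records=pd.DataFrame(
        records, columns=["sgrna", "gene", "cellline", "fold_change"]))

    # drug-target list: every hub plus decoy block genes
    target_genes: list[str] = []
    for b, members in enumerate(blocks):
        target_genes.append(hub_of_block[b])
        non_hub = [g for g in members if g != hub_of_block[b]]
        n_decoy = min(spec.decoy_targets_per_block, len(non_hub))
        decoys = rng.choice(non_hub, size=n_decoy, replace=False)
        target_genes.extend(sorted(decoys))
    annotation = {hub: "planted_hub" for hub in hub_of_block.values()}
    targets = GeneList(genes=target_genes, annotation=annotation)

    hubs_sorted = sorted(hub_of_block.values(),
                         key=lambda g: -abs(essentiality[g]))
    truth = GroundTruth(block_of_gene=block_of_gene,
                        overexpressed=set(block_of_gene),
                        hub_of_block=hub_of_block,
                        expected_hub_order=hubs_sorted,
                        essentiality=essentiality)
    return matrices, ppi, sgrna, targets, truth


@dataclass
class EndToEndReport:
    ari: float
    K: int
    n_selected: int
    n_network: int
    hub_cluster_rank: dict[str, int]   # hub -> rank among its cluster's targets
    all_hubs_first: bool
    ranking: "pd.DataFrame"


def end_to_end_fixture(spec: SyntheticSpec, knn_k: int = 10,
                       alpha: float = 0.05, k_max: int = 10) -> EndToEndReport:
    """Run the full pipeline on one synthetic study and compare to truth.

    Reports the adjusted Rand index between the recovered clustering and
    the planted blocks (restricted to block genes present in the
    clustering) and, for each planted hub, its |TI| rank among the targets
    of its own cluster.
    """
    from sklearn.metrics import adjusted_rand_score

    from .diffexpr import select_overexpressed
    from .network import build_cellline_network, build_tissue_network
    from .preprocess import (collapse_probes, essentiality_from_sgrna,
                             filter_probes, knn_impute, quantile_normalize)
    from .spectral import spectral_cluster
    from .tiscore import rank_targets

    matrices, ppi, sgrna, targets, truth = generate(spec)

    def prep(pm: ProbeMatrix):
        pm = filter_probes(pm)
        pm = knn_impute(pm, k=knn_k)
        em = collapse_probes(pm)
        return quantile_normalize(em)

    tissue = prep(matrices["tumor_normal"])
    cellline = prep(matrices["cellline"])
    diff = select_overexpressed(tissue, alpha=alpha)
    tissue_net = build_tissue_network(tissue, diff, ppi)
    ess = essentiality_from_sgrna(sgrna)
    cl_net = build_cellline_network(cellline, tissue_net, ess)
    assignment = spectral_cluster(tissue_net, seed=spec.seed, k_max=k_max)
    table = rank_targets(cl_net, assignment, targets)

    in_truth = [g for g in assignment.assignment if g in truth.block_of_gene]
    ari = adjusted_rand_score([truth.block_of_gene[g] for g in in_truth],
                              [assignment.assignment[g] for g in in_truth])

    frame = table.to_frame()
    hub_cluster_rank: dict[str, int] = {}
    for hub in truth.hub_of_block.values():
        row = frame[frame["gene"] == hub]
        if len(row) == 0:
            hub_cluster_rank[hub] = -1  # hub lost before ranking
            continue
        c = int(row["cluster_id"].iloc[0])
        in_cluster = frame[frame["cluster_id"] == c].sort_values(
            ["abs_TI", "gene"], ascending=[False, True])
        hub_cluster_rank[hub] = int(
            (in_cluster["gene"] == hub).to_numpy().nonzero()[0][0]) + 1
    all_first = all(r == 1 for r in hub_cluster_rank.values())
    return EndToEndReport(ari=float(ari), K=assignment.K,
                          n_selected=len(diff), n_network=len(tissue_net.nodes),
                          hub_cluster_rank=hub_cluster_rank,
                          all_hubs_first=all_first, ranking=frame)
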