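"""Readers and writers for every external file the pipeline touches.

Formats are deliberately plain: TSV expression matrices (genes in rows),
two-column sample-label TSVs, the STRING protein-links dialect for PPI
edges, a four-column sgRNA fold-change TSV, and one-symbol-per-line gene
lists. Missing expression values are written/parsed as ``NA`` (empty
cells also parse as missing).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datatypes import ExpressionMatrix, GeneList, PPIEdgeList, ProbeMatrix, SgRNATable

logger = logging.getLogger(__name__)

MISSING_MARKERS = ("NA", "")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, group) TSV into a label map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        raise ValueError(f"duplicate sample in label file {path}")
    return dict(zip(df["sample"], df["group"]))


def _read_matrix(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ValueError(f"repeated sample column in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(MISSING_MARKERS),
                     keep_default_na=False)
    df.index.name = None
    df.columns.name = None
    if df.index.has_duplicates:
        raise ValueError(f"repeated row id in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return df


def read_expression(path: str | Path, label_path: str | Path) -> ExpressionMatrix:
    """Read a gene-level expression TSV plus its sample-label file."""
    values = _read_matrix(path)
    labels = read_labels(label_path)
    unlabeled = [s for s in values.columns if s not in labels]
    if unlabeled:
        raise ValueError(f"samples missing from label file: {unlabeled[:5]}")
    return ExpressionMatrix(values=values, group_labels=labels)


def read_probe_matrix(path: str | Path, label_path: str | Path,
                      probe_map_path: str | Path | None = None) -> ProbeMatrix:
    """Read a probe-level expression TSV, labels, and optional probe→gene map."""
    values = _read_matrix(path)
    labels = read_labels(label_path)
    unlabeled = [s for s in values.columns if s not in labels]
    if unlabeled:
        raise ValueError(f"samples missing from label file: {unlabeled[:5]}")
    probe_to_gene = None
    if probe_map_path is not None:
        m = pd.read_csv(probe_map_path, sep="\t", header=None,
                        names=["probe", "gene"], dtype=str, comment="#")
        probe_to_gene = dict(zip(m["probe"], m["gene"]))
    return ProbeMatrix(values=values, group_labels=labels, probe_to_gene=probe_to_gene)


def write_expression(m: ExpressionMatrix, path: str | Path,
                     label_path: str | Path | None = None) -> None:
    m.values.to_csv(path, sep="\t", na_rep="NA", index_label="gene")
    if label_path is not None:
        with open(label_path, "w") as fh:
            for s in m.sample_ids:
                fh.write(f"{s}\t{m.group_labels[s]}\n")


def read_ppi(path: str | Path, min_score: int = 0) -> PPIEdgeList:
    """Read a STRING-style protein-links file (protein1 protein2 combined_score).

    Whitespace-separated; a header row is detected and skipped. Self-loops
    are dropped, duplicate unordered pairs are collapsed (max score kept),
    and edges scoring below ``min_score`` are removed.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"PPI file {path} needs 3 columns (protein1 protein2 combined_score)")
    # header row: third field not an integer
    first = str(df.iloc[0, 2]) if len(df) else ""
    try:
        int(first)
    except ValueError:
        df = df.iloc[1:]
    scores: dict[tuple[str, str], int] = {}
    n_self = 0
    for a, b, s in df.iloc[:, :3].itertuples(index=False):
        if a == b:
            n_self += 1
            continue
        score = int(s)
        if score < min_score:
            continue
        key = (a, b) if a < b else (b, a)
        if key in scores:
            scores[key] = max(scores[key], score)
        else:
            scores[key] = score
    if n_self:
        logger.warning("dropped %d self-interactions from %s", n_self, path)
    return PPIEdgeList(scores=scores)


def read_sgrna(path: str | Path) -> SgRNATable:
    """Read a four-column sgRNA TSV (sgrna, gene, cellline, fold_change)."""
    df = pd.read_csv(path, sep="\t", dtype={"sgrna": str, "gene": str, "cellline": str})
    if len(df) == 0:
        logger.warning("sgRNA file %s is empty (header only)", path)
    return SgRNATable(records=df)


def write_sgrna(t: SgRNATable, path: str | Path) -> None:
    t.records.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> GeneList:
    """Read a one-symbol-per-line gene list; an optional second tab-separated
    field becomes a free-text annotation."""
    genes: list[str] = []
    annotation: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            genes.append(parts[0])
            if len(parts) > 1 and parts[1]:
                annotation[parts[0]] = parts[1]
    return GeneList(genes=genes, annotation=annotation)


def write_gene_list(gl: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in gl.genes:
            if g in gl.annotation:
                fh.write(f"{g}\t{gl.annotation[g]}\n")
            else:
                fh.write(f"{g}\n")


def write_ppi(ppi: PPIEdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for (a, b), s in sorted(ppi.scores.items()):
            fh.write(f"{a} {b} {s}\n")


def write_clusters(assignment: dict[str, int], path: str | Path) -> None:
    """Write a gene→cluster map as a (gene, cluster_id) TSV."""
    if not assignment:
        raise ValueError("empty cluster assignment")
    with open(path, "w") as fh:
        fh.write("gene\tcluster_id\n")
        for g in sorted(assignment):
            fh.write(f"{g}\t{assignment[g]}\n")


def read_clusters(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cluster_id": int})
    return dict(zip(df["gene"], df["cluster_id"]))


RANKED_COLUMNS = ["gene", "cluster_id", "TI", "abs_TI", "rank", "reachable_count"]


def write_ranked_targets(table: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked target table (gene, cluster_id, TI, |TI|, rank, reachable_count)."""
    if len(table) == 0:
        raise ValueError("empty ranked target table")
    table[RANKED_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ranked_targets(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str})
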