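"""Core in-memory containers shared across the pipeline.

All downstream stages (differential expression, network construction,
spectral clustering, target scoring) operate on these types only; file
formats are confined to :mod:`scnrank.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = ("tumor", "normal", "cellline")


@dataclass
class ExpressionMatrix:
    """Gene-level expression: genes in rows, samples in columns.

    Values are log2-scale expression (or raw intensities prior to the
    log2 step); NaN marks missing entries. Every sample carries a group
    label in {tumor, normal, cellline}.
    """

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        missing = [s for s in cols if s not in self.group_labels]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        bad = {s: g for s, g in self.group_labels.items()
               if s in cols and g not in VALID_GROUPS}
        if bad:
            raise ValueError(f"invalid group labels (expect one of {VALID_GROUPS}): {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_labels[s] == group]

    def subset_group(self, group: str) -> pd.DataFrame:
        """View of the value matrix restricted to one sample group."""
        return self.values[self.samples_in_group(group)]


@dataclass
class ProbeMatrix:
    """Probe-level expression with an optional probe→gene annotation.

    ``probe_to_gene`` may be many-to-one and may omit probes (unmapped
    probes are dropped at collapse time).
    """

    values: pd.DataFrame  # index = probe ids, columns = sample ids
    group_labels: dict[str, str]
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.group_labels]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PPIEdgeList:
    """Undirected protein-protein interaction skeleton.

    Edges are unordered symbol pairs stored with min(a,b) first; scores
    follow the STRING combined-score convention (integers, 0-1000).
    """

    scores: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), s in self.scores.items():
            if a == b:
                raise ValueError(f"self-interaction not allowed: {a}")
            if (min(a, b), max(a, b)) != (a, b):
                raise ValueError(f"edge {(a, b)} not in canonical order")
            if s < 0:
                raise ValueError(f"negative score on edge {(a, b)}")

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.scores)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.scores:
            out.add(a)
            out.add(b)
        return out

    def has_edge(self, a: str, b: str) -> bool:
        return (min(a, b), max(a, b)) in self.scores


@dataclass
class SgRNATable:
    """Guide-level CRISPR knockout fold changes.

    One record per (sgRNA, cell line): the survival fold change observed
    after knocking out the guide's gene in that cell line.
    """

    records: pd.DataFrame  # columns: sgrna, gene, cellline, fold_change

    REQUIRED = ("sgrna", "gene", "cellline", "fold_change")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise ValueError(f"sgRNA table missing column {col!r}")
        fc = self.records["fold_change"].to_numpy(dtype=float)
        if not np.all(np.isfinite(fc)):
            raise ValueError("non-finite fold change in sgRNA table")
        if self.records.duplicated(subset=["sgrna", "cellline"]).any():
            raise ValueError("duplicate (sgrna, cellline) pair in sgRNA table")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneList:
    """Ordered set of gene symbols, e.g. drug-target genes."""

    genes: list[str]
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in gene list")
        if any(not g for g in self.genes):
            raise ValueError("empty gene symbol in gene list")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)
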