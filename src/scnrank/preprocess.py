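"""Expression and CRISPR preprocessing.

Probe-level microarray matrices are filtered (probes with more than 20%
missing data dropped), imputed (K-nearest-neighbour over probes, K=10),
collapsed probe→gene by averaging, quantile-normalised across samples and
log2-transformed. Guide-level CRISPR fold changes are aggregated to a
per-gene essentiality value: mean over a gene's sgRNAs within each cell
line, then mean over the cell lines in which the gene was screened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer

from .datatypes import ExpressionMatrix, ProbeMatrix, SgRNATable

logger = logging.getLogger(__name__)


@dataclass
class EssentialityTable:
    """Gene-level CRISPR essentiality (knockout survival fold change).

    Negative values mean the knockout reduced survival, i.e. the gene is
    essential in that context.
    """

    essentiality: dict[str, float]
    per_cellline: pd.DataFrame | None = None  # columns: gene, cellline, fold_change

    def __post_init__(self) -> None:
        bad = [g for g, v in self.essentiality.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite essentiality for genes: {bad[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.essentiality)

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.essentiality.get(gene, default)


def filter_probes(m: ProbeMatrix, max_missing_frac: float = 0.20) -> ProbeMatrix:
    """Drop probes whose missing fraction strictly exceeds ``max_missing_frac``.

    A probe with exactly the threshold fraction missing is kept ("more
    than" is a strict inequality). Probe order is preserved.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = m.values.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_probes: dropped %d/%d probes (> %.0f%% missing)",
                    n_drop, len(m.values), 100 * max_missing_frac)
    mapping = None
    if m.probe_to_gene is not None:
        kept = set(m.values.index[keep])
        mapping = {p: g for p, g in m.probe_to_gene.items() if p in kept}
    return ProbeMatrix(values=m.values.loc[keep].copy(),
                       group_labels=dict(m.group_labels),
                       probe_to_gene=mapping)


def knn_impute(m: ProbeMatrix, k: int = 10) -> ProbeMatrix:
    """Fill missing cells from the K nearest probes (rows).

    Neighbours are ranked by Euclidean distance over the columns both
    probes observe, rescaled by the fraction of shared observed columns
    (nan-Euclidean); the imputed value is the plain average of the
    neighbours' values in the missing column. Observed cells are never
    modified. K is clamped to the number of available neighbour rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = m.values
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        bad = values.index[all_missing].tolist()
        raise ValueError(f"probes with all entries missing cannot be imputed: {bad[:5]}")
    if not values.isna().any().any():
        return ProbeMatrix(values=values.copy(), group_labels=dict(m.group_labels),
                           probe_to_gene=dict(m.probe_to_gene) if m.probe_to_gene else None)
    n_neighbors = min(k, len(values) - 1)
    if n_neighbors < k:
        logger.warning("knn_impute: k=%d clamped to %d available neighbours", k, n_neighbors)
    imputer = KNNImputer(n_neighbors=n_neighbors, weights="uniform")
    filled = imputer.fit_transform(values.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=values.index, columns=values.columns)
    # observed entries must pass through untouched
    mask = values.notna()
    out = out.where(~mask, values)
    return ProbeMatrix(values=out, group_labels=dict(m.group_labels),
                       probe_to_gene=dict(m.probe_to_gene) if m.probe_to_gene else None)


def collapse_probes(m: ProbeMatrix) -> ExpressionMatrix:
    """Average probes mapping to the same gene; drop unmapped probes."""
    if m.probe_to_gene is None:
        raise ValueError("collapse_probes requires a probe->gene annotation")
    if m.values.isna().any().any():
        raise ValueError("collapse_probes requires a fully imputed matrix")
    mapped = [p for p in m.values.index if p in m.probe_to_gene]
    n_unmapped = len(m.values) - len(mapped)
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)
    sub = m.values.loc[mapped]
    genes = pd.Index([m.probe_to_gene[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes, sort=True).mean()
    return ExpressionMatrix(values=collapsed, group_labels=dict(m.group_labels))


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common quantile distribution.

    The reference distribution is the row-wise mean of the per-column
    sorted value vectors; ties within a column receive the mean of their
    quantile values (average-rank convention).
    """
    x = m.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile_normalize requires no missing entries")
    out = pd.DataFrame(quantile_normalize_array(x),
                       index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=out, group_labels=dict(m.group_labels))


def quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    """Quantile-normalise the columns of a dense (rows × columns) array."""
    n, p = x.shape
    if p == 1:
        return x.copy()
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    grid = np.arange(n, dtype=float)
    for j in range(p):
        ranks = rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return out


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset); errors name the offending cell."""
    shifted = m.values + offset
    bad = shifted <= 0
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        g = m.values.index[rows[0]]
        s = m.values.columns[cols[0]]
        raise ValueError(
            f"log2_transform: non-positive argument at gene {g!r}, sample {s!r} "
            f"(value {m.values.loc[g, s]!r} with offset {offset})")
    return ExpressionMatrix(values=np.log2(shifted), group_labels=dict(m.group_labels))


def essentiality_from_sgrna(t: SgRNATable) -> EssentialityTable:
    """Aggregate sgRNA fold changes to gene-level essentiality.

    Two-step mean: first over a gene's sgRNAs within each cell line, then
    over the cell lines in which the gene was screened (a mean of
    per-cell-line means, not a pooled guide mean).
    """
    if len(t) == 0:
        raise ValueError("cannot aggregate an empty sgRNA table")
    per_cl = (t.records.groupby(["gene", "cellline"], sort=True)["fold_change"]
              .mean().reset_index())
    gene_level = per_cl.groupby("gene", sort=True)["fold_change"].mean()
    return EssentialityTable(essentiality=gene_level.to_dict(), per_cellline=per_cl)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalisation as a scikit-learn transformer.

    ``fit`` learns the reference distribution (row-mean of sorted columns)
    from the training matrix; ``transform`` maps each column of new data
    onto that reference by rank. With the default ``refit_on_transform``
    the transformer behaves like the classic whole-matrix normalisation.

    Samples are columns here, matching the expression-matrix convention.
    """

    def __init__(self, refit_on_transform: bool = True):
        self.refit_on_transform = refit_on_transform

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        self.reference_ = np.sort(X, axis=0).mean(axis=1)
        self.n_rows_ = X.shape[0]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.refit_on_transform:
            self.fit(X)
        if X.shape[0] != self.n_rows_:
            raise ValueError("row count differs from fitted reference")
        grid = np.arange(self.n_rows_, dtype=float)
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            ranks = rankdata(X[:, j], method="average") - 1.0
            out[:, j] = np.interp(ranks, grid, self.reference_)
        return out
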