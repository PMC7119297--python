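"""Tumor-vs-normal differential expression.

Genes significantly over-expressed in tumor tissue (unpaired two-sided
t-test, p < alpha, positive log2 fold change) seed the tissue network;
their log fold change — the difference of log2 group means — becomes the
node weight. The raw p-value cutoff is deliberate (no multiple-testing
correction by default); a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiffExprResult:
    gene_id: str
    mean_tumor: float
    mean_normal: float
    log_fc: float  # mean_tumor - mean_normal, both on log2 scale
    t_stat: float
    p_value: float


def unpaired_ttest(x: np.ndarray, y: np.ndarray, variant: str = "welch"
                   ) -> tuple[float, float]:
    """Two-sided unpaired t-test; sign of t follows mean(x) - mean(y).

    ``variant`` is "welch" (unequal variances, default) or "student"
    (pooled variance). Two groups with zero variance and equal means
    return (0, 1) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 samples")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        logger.debug("degenerate t-test: zero variance, equal means -> t=0, p=1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(t), float(p)


def select_overexpressed(m: ExpressionMatrix, alpha: float = 0.05,
                         variant: str = "welch",
                         bh_correct: bool = False) -> list[DiffExprResult]:
    """Return genes significantly over-expressed in tumor vs normal.

    A gene is selected when its (two-sided) p-value is below ``alpha``
    AND its log fold change is positive. Results are ordered by gene id.
    With ``bh_correct`` the cutoff applies to Benjamini-Hochberg adjusted
    p-values instead (the reported p_value stays raw).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    tumor = m.subset_group("tumor")
    normal = m.subset_group("normal")
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need >= 2 tumor and >= 2 normal samples")
    pvals = np.empty(len(m.values))
    rows: list[DiffExprResult] = []
    for i, gene in enumerate(m.values.index):
        x = tumor.loc[gene].to_numpy(dtype=float)
        y = normal.loc[gene].to_numpy(dtype=float)
        t, p = unpaired_ttest(x, y, variant=variant)
        mt, mn = float(np.mean(x)), float(np.mean(y))
        rows.append(DiffExprResult(gene_id=gene, mean_tumor=mt, mean_normal=mn,
                                   log_fc=mt - mn, t_stat=t, p_value=p))
        pvals[i] = p
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        selected = [r for r, rej in zip(rows, reject) if rej and r.log_fc > 0]
    else:
        logger.info("select_overexpressed: raw p < %.3g cutoff, no multiple-testing "
                    "correction", alpha)
        selected = [r for r in rows if r.p_value < alpha and r.log_fc > 0]
    selected.sort(key=lambda r: r.gene_id)
    logger.info("select_overexpressed: %d/%d genes over-expressed at alpha=%.3g",
                len(selected), len(rows), alpha)
    return selected


def results_to_frame(results: list[DiffExprResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results],
                        columns=["gene_id", "mean_tumor", "mean_normal",
                                 "log_fc", "t_stat", "p_value"])
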