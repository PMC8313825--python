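"""Immune-related lncRNA screening and tumor-vs-normal differential expression.

An lncRNA is *immune-related* (irlncRNA) when its log-scale expression
correlates with at least one curated immune gene past a Pearson threshold
(default r > 0.4 at p < 0.001, no multiplicity correction — the raw-p rule is
deliberate). Differential expression between tumor and normal uses the
Wilcoxon rank-sum test on log2(x+1) with Benjamini–Hochberg FDR; genes pass
at |log2FC| > 1 and FDR < 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = [
    "CorrelationScreen",
    "screen_irlncrnas",
    "DifferentialExpression",
    "differential_expression",
]


@dataclass
class CorrelationScreen:
    """Result of the irlncRNA co-expression screen."""

    retained: list[str]
    results: pd.DataFrame  # lnc_id, immune_gene_id, r, p
    n_skipped_zero_variance: int = 0


def _pearson_with_p(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of vector x against each row of Y, with the t-transform p-value.

    p = 2 * P(T_{n-2} > |t|) where t = r * sqrt((n-2) / (1-r^2)).
    """
    n = x.size
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ xc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def screen_irlncrnas(
    expr: ExpressionMatrix,
    lnc_ids: Sequence[str],
    immune_ids: Sequence[str],
    r_min: float = 0.4,
    p_max: float = 0.001,
    abs_cor: bool = False,
) -> CorrelationScreen:
    """Retain lncRNAs correlated with at least one immune gene.

    Pearson r is computed on log2(x+1) across all samples (tumor and normal)
    for every (lncRNA, immune gene) couple. By default ``r > r_min`` is read
    literally as positive correlation; set ``abs_cor`` for |r| > r_min.
    Zero-variance genes make r undefined for their couples; those couples are
    skipped and counted, never raised.
    """
    if expr.n_samples < 3:
        raise ValueError("correlation screen requires at least 3 samples")
    lnc_ids = [g for g in lnc_ids if g in expr.values.index]
    immune_ids = [g for g in immune_ids if g in expr.values.index]
    if not lnc_ids or not immune_ids:
        raise ValueError("both the lncRNA and immune gene sets must be present in the matrix")
    logx = np.log2(expr.values.to_numpy(dtype=float) + 1.0)
    row = {g: i for i, g in enumerate(expr.gene_ids)}
    L = logx[[row[g] for g in lnc_ids]]
    M = logx[[row[g] for g in immune_ids]]
    lnc_var = L.var(axis=1) > 0
    imm_var = M.var(axis=1) > 0

    retained: list[str] = []
    records = []
    n_skipped = int((~lnc_var).sum()) * len(immune_ids) + int(lnc_var.sum()) * int((~imm_var).sum())
    Mv = M[imm_var]
    imm_names = [g for g, ok in zip(immune_ids, imm_var) if ok]
    for lnc, ok, x in zip(lnc_ids, lnc_var, L):
        if not ok or not imm_names:
            continue
        r, p = _pearson_with_p(x, Mv)
        eff = np.abs(r) if abs_cor else r
        hit = (eff > r_min) & (p < p_max)
        if hit.any():
            retained.append(lnc)
        records.append(
            pd.DataFrame({"lnc_id": lnc, "immune_gene_id": imm_names, "r": r, "p": p})
        )
    results = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["lnc_id", "immune_gene_id", "r", "p"])
    )
    return CorrelationScreen(retained=retained, results=results, n_skipped_zero_variance=n_skipped)


@dataclass
class DifferentialExpression:
    """Per-gene tumor-vs-normal DE results with BH-adjusted p-values."""

    table: pd.DataFrame  # gene_id (index), log2fc, p, fdr, direction, de

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["de"]])

    @property
    def n_up(self) -> int:
        return int((self.table["de"] & (self.table["direction"] == "up")).sum())

    @property
    def n_down(self) -> int:
        return int((self.table["de"] & (self.table["direction"] == "down")).sum())


def differential_expression(
    expr: ExpressionMatrix,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    engine: str = "wilcoxon",
) -> DifferentialExpression:
    """Call tumor-vs-normal differential expression on log2(x+1) values.

    log2FC is the difference of group means of log2(x+1); the p-value comes
    from the two-sided Wilcoxon rank-sum test (``engine="wilcoxon"``) or a
    Welch t-test (``engine="welch"``); FDR is Benjamini–Hochberg over all
    tested genes. A gene is DE iff |log2FC| > lfc_min and FDR < fdr_max.
    """
    tumor = expr.samples_in_group("tumor")
    normal = expr.samples_in_group("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("differential expression requires >= 2 samples per group")
    logx = expr.log2p1()
    T = logx[tumor].to_numpy()
    N = logx[normal].to_numpy()
    log2fc = T.mean(axis=1) - N.mean(axis=1)
    if engine == "wilcoxon":
        # zero-variance rows make ranksums p = 1 (all ties), which is fine
        stat, p = stats.ranksums(T, N, axis=1)
    elif engine == "welch":
        stat, p = stats.ttest_ind(T, N, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
    else:
        raise ValueError(f"unknown DE engine {engine!r}")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    direction = np.where(log2fc > 0, "up", "down")
    de = (np.abs(log2fc) > lfc_min) & (fdr < fdr_max)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "direction": direction, "de": de},
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    return DifferentialExpression(table)
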