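"""Stratified clinical, immune and drug-sensitivity comparisons.

All group comparisons between independent high/low risk groups use the
Wilcoxon rank-sum (Mann-Whitney) test — exact enumeration when both groups
have at most 25 observations and no ties, the normal approximation with
continuity correction otherwise. Categorical association uses the
chi-squared test without continuity correction; correlations are Spearman.
The significance flag threshold is p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .coxph import CoxFit, cox_fit
from .io import ClinicalTable, ExpressionMatrix
from .signature import RiskProfile

__all__ = [
    "AssociationResult",
    "InfiltrationTable",
    "DrugResponseTable",
    "DEFAULT_ORDINAL_MAP",
    "DEFAULT_ICI_GENES",
    "clinical_association",
    "independence_cox",
    "immune_correlation",
    "group_expression_compare",
    "drug_sensitivity_compare",
    "encode_ordinal",
]

SIGNIFICANCE = 0.05

#: Checkpoint-inhibitor marker genes compared between risk groups by default.
DEFAULT_ICI_GENES = ("CTLA4", "PDCD1", "LAG3", "TIGIT", "HAVCR2")

#: Ordinal encodings for stage-like clinical covariates (overridable).
DEFAULT_ORDINAL_MAP: dict[str, dict[str, int]] = {
    "stage": {"I": 1, "II": 2, "III": 3, "IV": 4,
              "Stage I": 1, "Stage II": 2, "Stage III": 3, "Stage IV": 4},
    "T": {"T1": 1, "T2": 2, "T3": 3, "T4": 4},
    "N": {"N0": 0, "N1": 1, "N2": 2, "N3": 3},
    "M": {"M0": 0, "M1": 1},
    "grade": {"G1": 1, "G2": 2, "G3": 3, "G4": 4},
    "gender": {"female": 0, "male": 1},
}


@dataclass
class AssociationResult:
    """One statistical comparison: feature, test, statistic, p, direction."""

    feature: str
    test: str
    statistic: float
    p: float
    direction: str = ""
    detail: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE


def _results_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature": r.feature, "test": r.test, "statistic": r.statistic,
             "p": r.p, "direction": r.direction, "significant": r.significant}
            for r in results
        ]
    )


@dataclass
class InfiltrationTable:
    """Long-format immune-infiltration scores: sample_id, cell_type, method, score."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample_id", "cell_type", "method", "score"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"infiltration table requires columns {sorted(need)}")

    @classmethod
    def from_tsv(cls, path) -> "InfiltrationTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class DrugResponseTable:
    """Long-format drug response: sample_id, drug, ic50."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample_id", "drug", "ic50"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"drug table requires columns {sorted(need)}")

    @classmethod
    def from_tsv(cls, path) -> "DrugResponseTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact when both n <= 25 and tie-free."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def clinical_association(
    profile: RiskProfile,
    clinical: ClinicalTable,
    features: Iterable[str] | None = None,
) -> list[AssociationResult]:
    """Risk group vs clinical categories: chi-squared plus rank tests on scores.

    Per categorical feature: (a) the chi-squared statistic sum((O-E)^2/E) on
    the risk-group x category contingency table ((r-1)(c-1) df, no continuity
    correction), categories with zero expected count dropped; (b) the risk
    score compared across categories by Wilcoxon rank-sum (2 groups) or
    Kruskal-Wallis (>2).
    """
    shared = [s for s in profile.scores.index if s in clinical.data.index]
    cl = clinical.data.loc[shared]
    grp = profile.group.loc[shared]
    scores = profile.scores.loc[shared]
    if features is None:
        features = clinical.covariate_names
    results: list[AssociationResult] = []
    for feat in features:
        vals = cl[feat].dropna()
        if vals.nunique() < 2:
            continue
        tab = pd.crosstab(grp.loc[vals.index], vals)
        tab = tab.loc[:, (tab.sum(axis=0) > 0)]
        if tab.shape[1] >= 2 and tab.to_numpy().sum() > 0:
            chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            results.append(
                AssociationResult(feat, "chi_squared", float(chi2), float(p),
                                  detail={"dof": int(dof), "table": tab})
            )
        levels = [scores.loc[vals.index[vals == lv]].to_numpy() for lv in vals.unique()]
        levels = [lv for lv in levels if lv.size > 0]
        if len(levels) == 2:
            stat, p = rank_sum_test(levels[0], levels[1])
            results.append(AssociationResult(feat, "wilcoxon_rank_sum", stat, p))
        elif len(levels) > 2:
            stat, p = stats.kruskal(*levels)
            results.append(AssociationResult(feat, "kruskal_wallis", float(stat), float(p)))
    return results


def encode_ordinal(
    clinical: ClinicalTable,
    ordinal_map: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Numeric design matrix from clinical covariates via the ordinal map.

    Numeric columns pass through; mapped categoricals become ordered
    integers; unmappable columns are skipped.
    """
    omap = dict(DEFAULT_ORDINAL_MAP)
    if ordinal_map:
        omap.update(ordinal_map)
    out = {}
    for col in clinical.covariate_names:
        s = clinical.data[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        elif col in omap:
            out[col] = s.map(omap[col]).astype(float)
    return pd.DataFrame(out, index=clinical.data.index)


def independence_cox(
    scores: pd.Series,
    clinical: ClinicalTable,
    ordinal_map: Mapping[str, Mapping[str, int]] | None = None,
    ties: str = "efron",
) -> tuple[list[CoxFit], CoxFit]:
    """Is the risk score prognostic independent of clinical covariates?

    Univariate Cox per covariate (risk score first), then one multivariate
    fit on all jointly. Rows with missing values are dropped casewise;
    collinear covariates are dropped (the later one) with a record in the
    multivariate fit's ``dropped`` list.
    """
    shared = [s for s in scores.index if s in clinical.data.index]
    cl = clinical.aligned_to(shared)
    design = encode_ordinal(cl, ordinal_map)
    design.insert(0, "risk_score", scores.loc[shared])
    keep = design.dropna().index
    design = design.loc[keep]
    times = cl.data.loc[keep, "os_time"].to_numpy(dtype=float)
    events = cl.data.loc[keep, "os_event"].to_numpy(dtype=int)

    univariate = [
        cox_fit(times, events, design[[col]].to_numpy(), names=[col], ties=ties)
        for col in design.columns
    ]
    # drop exactly collinear columns (later ones) before the joint fit
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    kept_idx: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept_idx + [j]]
        if np.linalg.matrix_rank(trial - trial.mean(axis=0)) > len(kept_idx):
            kept_idx.append(j)
    dropped = [names[j] for j in range(X.shape[1]) if j not in kept_idx]
    multi = cox_fit(times, events, X[:, kept_idx], names=[names[j] for j in kept_idx], ties=ties)
    multi.dropped.extend(dropped)
    return univariate, multi


def immune_correlation(
    profile: RiskProfile, infil: InfiltrationTable
) -> list[AssociationResult]:
    """Spearman rho of score vs infiltration plus high/low rank-sum per (cell type, method)."""
    results: list[AssociationResult] = []
    for (cell, method), sub in infil.data.groupby(["cell_type", "method"]):
        sub = sub.set_index("sample_id")
        shared = [s for s in profile.scores.index if s in sub.index]
        if len(shared) < 3:
            continue
        x = profile.scores.loc[shared].to_numpy()
        y = sub.loc[shared, "score"].to_numpy(dtype=float)
        feat = f"{cell}[{method}]"
        if np.unique(y).size < 2:
            continue  # constant column: rho undefined, skipped
        rho, p = stats.spearmanr(x, y)
        results.append(
            AssociationResult(feat, "spearman", float(rho), float(p),
                              direction="negative" if rho < 0 else "positive")
        )
        hi = y[np.isin(shared, profile.high_samples)]
        lo = y[np.isin(shared, profile.low_samples)]
        if hi.size >= 2 and lo.size >= 2:
            stat, p = rank_sum_test(hi, lo)
            direction = "lower in high" if np.median(hi) < np.median(lo) else "higher in high"
            results.append(AssociationResult(feat, "wilcoxon_rank_sum", stat, p, direction))
    return results


def group_expression_compare(
    expr: ExpressionMatrix,
    profile: RiskProfile,
    gene_list: Iterable[str] = DEFAULT_ICI_GENES,
) -> list[AssociationResult]:
    """Rank-sum comparison of log2(x+1) expression between risk groups per gene.

    Genes absent from the matrix are reported (test "missing"), never fatal.
    """
    results: list[AssociationResult] = []
    logx = expr.log2p1()
    for gene in gene_list:
        if gene not in logx.index:
            results.append(AssociationResult(gene, "missing", float("nan"), float("nan")))
            continue
        hi = [s for s in profile.high_samples if s in logx.columns]
        lo = [s for s in profile.low_samples if s in logx.columns]
        x = logx.loc[gene, hi].to_numpy(dtype=float)
        y = logx.loc[gene, lo].to_numpy(dtype=float)
        stat, p = rank_sum_test(x, y)
        direction = "lower in high" if np.median(x) < np.median(y) else "higher in high"
        results.append(AssociationResult(gene, "wilcoxon_rank_sum", stat, p, direction))
    return results


def drug_sensitivity_compare(
    profile: RiskProfile, drugs: DrugResponseTable
) -> list[AssociationResult]:
    """Rank-sum IC50 comparison per drug; "lower in high" implies higher sensitivity."""
    results: list[AssociationResult] = []
    for drug, sub in drugs.data.groupby("drug"):
        sub = sub.set_index("sample_id")
        hi = [s for s in profile.high_samples if s in sub.index]
        lo = [s for s in profile.low_samples if s in sub.index]
        if len(hi) < 2 or len(lo) < 2:
            continue  # one group absent: skipped
        x = sub.loc[hi, "ic50"].to_numpy(dtype=float)
        y = sub.loc[lo, "ic50"].to_numpy(dtype=float)
        stat, p = rank_sum_test(x, y)
        direction = "lower in high" if np.median(x) < np.median(y) else "higher in high"
        results.append(AssociationResult(str(drug), "wilcoxon_rank_sum", stat, p, direction))
    return results
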