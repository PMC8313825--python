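"""Risk scoring, time-dependent ROC, AIC-optimal cutpoint, and stratification.

The risk score of a patient is the linear predictor sum(beta_i * C_i) over
the signature's pair indicators, with beta from the final multivariate Cox
fit. Discrimination for "death by time t" under censoring uses the
cumulative/dynamic ROC with inverse-probability-of-censoring weights (IPCW)
from the Kaplan-Meier estimate of the censoring distribution. The risk
cutoff is chosen by scanning candidate thresholds and minimizing the AIC of
the dichotomized single-covariate Cox fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxph import cox_fit, km_estimate
from .pairing import PairMatrix

__all__ = [
    "Signature",
    "RiskProfile",
    "TimedROC",
    "CutpointScan",
    "risk_score",
    "td_roc",
    "aic_cutpoint",
    "stratify",
]


@dataclass
class Signature:
    """Ordered (pair_id, beta) list defining the prognostic model."""

    pairs: list[tuple[str, float]]

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("signature pair ids must be distinct")
        for p, b in self.pairs:
            if not np.isfinite(b) or b == 0.0:
                raise ValueError(f"signature beta for {p!r} must be finite and nonzero")

    @property
    def pair_ids(self) -> list[str]:
        return [p for p, _ in self.pairs]

    @property
    def betas(self) -> np.ndarray:
        return np.array([b for _, b in self.pairs], dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)


def risk_score(pm: PairMatrix, sig: Signature) -> pd.Series:
    """Per-sample risk score sum(beta_i * C_i); missing pairs raise, never zero-fill."""
    missing = [p for p in sig.pair_ids if p not in pm.indicators.index]
    if missing:
        raise KeyError(f"signature pairs absent from pair matrix: {missing}")
    C = pm.indicators.loc[sig.pair_ids].to_numpy(dtype=float)
    scores = sig.betas @ C
    return pd.Series(scores, index=pm.sample_ids, name="risk_score")


@dataclass
class TimedROC:
    """Cumulative/dynamic ROC at evaluation time ``t_eval`` (days)."""

    t_eval: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "sensitivity": self.sensitivity,
             "specificity": self.specificity}
        )


def _censoring_km_left(times, events):
    """KM of the censoring distribution G and a left-limit evaluator G(t-)."""
    cens_curve = km_estimate(times, 1 - np.asarray(events, dtype=int))

    def G_left(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if cens_curve.event_times.size == 0:
            return np.ones_like(t)
        # left limit: product over censor times strictly below t
        idx = np.searchsorted(cens_curve.event_times, t, side="left") - 1
        return np.where(idx >= 0, cens_curve.survival[np.clip(idx, 0, None)], 1.0)

    return G_left


def td_roc(times, events, scores, t_eval: float) -> TimedROC:
    """IPCW cumulative/dynamic ROC and AUC at time ``t_eval``.

    Cases are subjects with an observed event by ``t_eval`` (weighted by
    1/G(T-), G the censoring KM); controls are subjects still under
    observation beyond ``t_eval`` (their common weight cancels). AUC is the
    trapezoidal area over the threshold sweep on observed score values; with
    no censoring it reduces exactly to the Mann-Whitney U statistic with ties
    counted one half.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    scores = np.asarray(scores, dtype=float)
    case = (times <= t_eval) & (events == 1)
    control = times > t_eval
    if case.sum() == 0:
        raise ValueError(f"no events observed by t={t_eval}")
    if control.sum() == 0:
        raise ValueError(f"no subjects under observation beyond t={t_eval}")
    G_left = _censoring_km_left(times, events)
    w_case = 1.0 / np.clip(G_left(times[case]), 1e-12, None)
    s_case = scores[case]
    s_ctrl = scores[control]

    thr = np.unique(scores)[::-1]  # descending: sweep from most extreme positive call
    # mass of cases/controls at each unique score value
    case_mass = np.zeros(thr.size)
    ctrl_mass = np.zeros(thr.size)
    pos_case = np.searchsorted(-thr, -s_case)
    np.add.at(case_mass, pos_case, w_case)
    pos_ctrl = np.searchsorted(-thr, -s_ctrl)
    np.add.at(ctrl_mass, pos_ctrl, 1.0)
    tpr = np.concatenate([[0.0], np.cumsum(case_mass) / w_case.sum()])
    fpr = np.concatenate([[0.0], np.cumsum(ctrl_mass) / s_ctrl.size])
    auc = float(np.trapezoid(tpr, fpr))
    return TimedROC(
        t_eval=float(t_eval),
        thresholds=thr,
        sensitivity=tpr[1:],
        specificity=1.0 - fpr[1:],
        auc=auc,
        n_cases=int(case.sum()),
        n_controls=int(control.sum()),
    )


@dataclass
class CutpointScan:
    """AIC per candidate risk cutoff; the chosen cutoff minimizes AIC."""

    candidates: np.ndarray
    aic: np.ndarray
    cutoff: float
    t_ref: float
    beta_at_cutoff: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.candidates, "aic": self.aic})


def aic_cutpoint(times, events, scores, t_ref: float = 1825.0,
                 min_group_frac: float = 0.1, ties: str = "efron") -> CutpointScan:
    """Choose the risk cutoff whose dichotomization minimizes Cox AIC.

    Candidates are midpoints between consecutive distinct sorted scores,
    restricted so each side keeps at least ``min_group_frac`` of the samples;
    for each candidate the single-covariate Cox model on the indicator
    score > c is fitted and its AIC recorded. AIC ties break toward the
    candidate nearest the median score. ``t_ref`` is carried for reporting
    (the ROC horizon the scan accompanies); it does not enter the AIC.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct scores")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = scores.size
    n_high = (scores[None, :] > mids[:, None]).sum(axis=1)
    ok = (n_high >= min_group_frac * n) & ((n - n_high) >= min_group_frac * n)
    cand = mids[ok]
    if cand.size == 0:
        raise ValueError(
            "all candidate cutoffs excluded by min_group_frac; lower min_group_frac"
        )
    aics = np.empty(cand.size)
    betas = np.empty(cand.size)
    for i, c in enumerate(cand):
        ind = (scores > c).astype(float)
        fit = cox_fit(times, events, ind[:, None], names=["high_risk"], ties=ties)
        aics[i] = fit.aic
        betas[i] = fit.beta[0] if fit.k else 0.0
    best = np.flatnonzero(aics <= aics.min() + 1e-12)
    if best.size > 1:
        med = np.median(scores)
        best = best[np.argmin(np.abs(cand[best] - med))]
    else:
        best = best[0]
    return CutpointScan(
        candidates=cand, aic=aics, cutoff=float(cand[best]), t_ref=float(t_ref),
        beta_at_cutoff=float(betas[best]),
    )


@dataclass
class RiskProfile:
    """Per-sample risk scores, the chosen cutoff, and high/low group labels."""

    scores: pd.Series
    cutoff: float
    group: pd.Series  # "high" / "low"

    @property
    def n_high(self) -> int:
        return int((self.group == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.group == "low").sum())

    @property
    def high_samples(self) -> list[str]:
        return list(self.group.index[self.group == "high"])

    @property
    def low_samples(self) -> list[str]:
        return list(self.group.index[self.group == "low"])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"risk_score": self.scores, "group": self.group})


def stratify(scores: pd.Series, cutoff: float) -> RiskProfile:
    """High/low grouping: high iff score > cutoff (strict)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = pd.Series(scores)
    group = pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index, name="group")
    return RiskProfile(scores=scores, cutoff=float(cutoff), group=group)
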