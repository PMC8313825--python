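"""Censored-survival numerics: Kaplan-Meier, log-rank, and Cox partial likelihood.

The Cox model is fitted by Newton-Raphson on the log partial likelihood with
the Efron tie correction (Breslow available). Standard errors come from the
inverse observed information; p-values and confidence intervals are Wald.
Monotone likelihood (perfect separation, diverging beta) is detected and
flagged rather than silently returning a huge coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "KMCurve",
    "cox_fit",
    "cox_loglik",
    "cox_score",
    "km_estimate",
    "logrank_test",
    "stepwise_cox",
    "univariate_pair_screen",
]

_BETA_DIVERGENCE = 20.0  # |beta| beyond this while loglik still improves => separation


def _prepare(times, events, X):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if times.ndim != 1 or times.size != events.size or X.shape[0] != times.size:
        raise ValueError("times, events and X must align on the sample axis")
    if (times <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be binary")
    order = np.argsort(times, kind="stable")
    return times[order], events[order], X[order]


def _loglik_grad_hess_notied(beta, times, events, X, want=2):
    """Vectorized partial likelihood for data without tied event times.

    With unique event times the Efron and Breslow corrections coincide and
    the risk-set sums reduce to reverse cumulative sums.
    """
    n, k = X.shape
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    S = np.cumsum(w[::-1])[::-1]
    ev = events == 1
    loglik = float(eta[ev].sum() - np.log(S[ev]).sum())
    if want == 0:
        return loglik
    M = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    mbar = M[ev] / S[ev, None]
    grad = X[ev].sum(axis=0) - mbar.sum(axis=0)
    if want == 1:
        return loglik, grad
    wxx = (w[:, None] * X)[:, :, None] * X[:, None, :]
    Q = np.cumsum(wxx[::-1], axis=0)[::-1]
    hess = -(Q[ev] / S[ev, None, None]).sum(axis=0) + np.einsum("ij,il->jl", mbar, mbar)
    return loglik, grad, hess


def _loglik_grad_hess(beta, times, events, X, ties="efron", want=2):
    """Log partial likelihood and derivatives; inputs must be sorted by time.

    ``want``: 0 loglik only, 1 +gradient, 2 +hessian (of the loglik, i.e.
    negative definite).
    """
    n, k = X.shape
    ev_times = times[events == 1]
    if ev_times.size == np.unique(ev_times).size and not np.isin(ev_times, times[events == 0]).any():
        # no event time is tied with any other observation time
        return _loglik_grad_hess_notied(beta, times, events, X, want)
    eta = X @ beta
    eta = eta - eta.max()  # affine shift cancels in every risk-set ratio
    w = np.exp(eta)
    wx = w[:, None] * X
    # reverse cumulative risk-set sums: entry i = sum over j >= i
    S = np.cumsum(w[::-1])[::-1]
    M = np.cumsum(wx[::-1], axis=0)[::-1]
    if want >= 2:
        wxx = wx[:, :, None] * X[:, None, :]
        Q = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        d_idx = np.arange(i, j)[events[i:j] == 1]
        d = d_idx.size
        if d > 0:
            S_R, M_R = S[i], M[i]
            loglik += eta[d_idx].sum()
            grad_add = X[d_idx].sum(axis=0) if want >= 1 else None
            if ties == "breslow" or d == 1:
                ls = np.arange(d)
                if ties == "breslow":
                    fracs = np.zeros(d)
                else:
                    fracs = ls / d
            else:
                fracs = np.arange(d) / d
            S_D = w[d_idx].sum()
            M_D = wx[d_idx].sum(axis=0) if want >= 1 else None
            for f in fracs:
                phi = S_R - f * S_D
                loglik -= np.log(phi)
                if want >= 1:
                    m = M_R - f * M_D
                    grad -= m / phi
                if want >= 2:
                    V = Q[i] - f * wxx[d_idx].sum(axis=0)
                    hess -= V / phi - np.outer(m, m) / phi**2
            if want >= 1:
                grad += grad_add
        i = j
    if want == 0:
        return loglik
    if want == 1:
        return loglik, grad
    return loglik, grad, hess


def cox_loglik(beta, times, events, X, ties="efron") -> float:
    """Log partial likelihood at ``beta`` (Efron or Breslow ties)."""
    times, events, X = _prepare(times, events, X)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    return float(_loglik_grad_hess(beta, times, events, X, ties, want=0))


def cox_score(beta, times, events, X, ties="efron") -> np.ndarray:
    """Score vector (gradient of the log partial likelihood) at ``beta``."""
    times, events, X = _prepare(times, events, X)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    _, grad = _loglik_grad_hess(beta, times, events, X, ties, want=1)
    return grad


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``beta`` are log hazard ratios; ``hr = exp(beta)``; ``ci95`` the Wald 95%
    interval on the hazard-ratio scale; ``p`` two-sided Wald p-values.
    ``aic = 2k - 2 loglik``. ``dropped`` lists covariates excluded as
    unidentifiable (zero variance).
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    ties_method: str
    n: int
    n_events: int
    converged: bool = True
    monotone_likelihood: bool = False
    dropped: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        half = 1.959963984540054 * self.se
        return np.exp(np.column_stack([self.beta - half, self.beta + half]))

    @property
    def p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def k(self) -> int:
        return len(self.beta)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def summary(self) -> pd.DataFrame:
        ci = self.ci95 if self.k else np.empty((0, 2))
        return pd.DataFrame(
            {
                "beta": self.beta,
                "HR": self.hr,
                "HR_ci_low": ci[:, 0],
                "HR_ci_high": ci[:, 1],
                "se": self.se,
                "p": self.p,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def cox_fit(times, events, X, names=None, ties: str = "efron", max_iter: int = 50) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with step-halving.

    Convergence when max|score| < 1e-9 or the relative log-likelihood change
    falls below 1e-12. Zero-variance covariates are dropped (reported in
    ``CoxFit.dropped``); diverging coefficients with still-improving
    likelihood set ``monotone_likelihood`` and clear ``converged``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    Xin = np.asarray(X, dtype=float)
    if Xin.ndim == 1:
        Xin = Xin[:, None]
    if names is None:
        names = [f"x{i}" for i in range(Xin.shape[1])]
    names = list(names)
    if np.isnan(Xin).any():
        raise ValueError("covariates contain missing values")
    keep = Xin.std(axis=0) > 0
    dropped = [nm for nm, k_ in zip(names, keep) if not k_]
    names = [nm for nm, k_ in zip(names, keep) if k_]
    Xk = Xin[:, keep]
    n, k = Xk.shape
    if k >= n:
        raise ValueError("need more samples than covariates")
    times_s, events_s, Xs = _prepare(times, events, Xk)
    n_events = int(events_s.sum())

    if k == 0:
        ll0 = _loglik_grad_hess(np.zeros(0), times_s, events_s, Xs, ties, want=0)
        return CoxFit([], np.zeros(0), np.zeros(0), float(ll0), ties, n, n_events, dropped=dropped)

    # center for numerical stability; partial likelihood is shift-invariant
    mu = Xs.mean(axis=0)
    Xc = Xs - mu
    beta = np.zeros(k)
    ll, grad, hess = _loglik_grad_hess(beta, times_s, events_s, Xc, ties, want=2)
    converged = False
    monotone = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < 1e-9:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll = _loglik_grad_hess(new_beta, times_s, events_s, Xc, ties, want=0)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik_grad_hess(new_beta, times_s, events_s, Xc, ties, want=0)
            halvings += 1
            if halvings > 30:
                break
        improving = new_ll > ll
        rel_change = abs(new_ll - ll) / max(1.0, abs(ll))
        beta, prev_ll = new_beta, ll
        ll, grad, hess = _loglik_grad_hess(beta, times_s, events_s, Xc, ties, want=2)
        if np.max(np.abs(beta)) > _BETA_DIVERGENCE and improving:
            monotone = True
            converged = False
            break
        if rel_change < 1e-12:
            converged = np.max(np.abs(grad)) < 1e-3 or abs(ll - prev_ll) < 1e-12
            break
    else:
        converged = np.max(np.abs(grad)) < 1e-6
    if not monotone and np.max(np.abs(grad)) < 1e-9:
        converged = True

    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return CoxFit(
        names, beta, se, float(ll), ties, n, n_events,
        converged=converged, monotone_likelihood=monotone, dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct times with >= 1 event; ``survival`` the
    estimate S(t) just after each; ``at_risk``/``n_events`` per event time;
    ``censor_times`` the observed censoring times (for tick marks).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """S(t) via right-continuous step interpolation (S = 1 before the first event)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.event_times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.event_times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.n_events}
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times <= 0).any():
        raise ValueError("times must be strictly positive")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    at_risk_all = t.size - first  # subjects with time >= uniq (sorted)
    mask = d > 0
    ev_times = uniq[mask]
    d_ev = d[mask]
    n_ev = at_risk_all[mask]
    surv = np.cumprod(1.0 - d_ev / n_ev)
    return KMCurve(ev_times, surv, n_ev, d_ev, times[events == 0])


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df.

    At each event time the observed minus hypergeometric-expected events in
    group 1 are accumulated; the variance sum is hypergeometric. When neither
    group has any event the statistic is 0 and p = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group).astype(int)
    if len(np.unique(group)) > 2:
        raise ValueError("logrank_test is two-group; got more levels")
    if (group == 1).sum() == 0 or (group == 0).sum() == 0:
        raise ValueError("both groups must be non-empty")
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], group[order]
    uniq, first = np.unique(t, return_index=True)
    n_at = t.size - first
    n1_at = np.cumsum(g[::-1])[::-1][first]
    d = np.add.reduceat(e, first)
    d1 = np.add.reduceat(e * g, first)
    mask = d > 0
    if not mask.any():
        return 0.0, 1.0
    n, n1, dd, dd1 = n_at[mask], n1_at[mask], d[mask], d1[mask]
    expected = dd * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = dd * (n1 / n) * (1 - n1 / n) * (n - dd) / np.maximum(n - 1, 1)
    var = np.where(n > 1, var, 0.0)
    O_E = (dd1 - expected).sum()
    V = var.sum()
    if V <= 0:
        return 0.0, 1.0
    chi2 = O_E**2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# screening and model selection built on cox_fit


def univariate_pair_screen(pm, clinical, p_max: float = 0.05, ties: str = "efron"):
    """Single-covariate Cox fit per pair indicator; retain Wald p < p_max.

    ``pm`` is a :class:`~lncpair.pairing.PairMatrix`; ``clinical`` a
    :class:`~lncpair.io.ClinicalTable`. Samples must match exactly (order is
    reconciled here; genuinely unmatched samples raise). Unidentifiable or
    non-converged fits are dropped and counted.

    Returns ``(hits, report)`` with ``hits`` a list of (pair_id, CoxFit)
    sorted by p, and ``report`` a dict of counts.
    """
    pm_samples = set(pm.sample_ids)
    cl_samples = set(clinical.sample_ids)
    if pm_samples != cl_samples:
        missing = sorted(pm_samples ^ cl_samples)
        raise ValueError(f"sample mismatch between pair matrix and clinical table: {missing[:10]}")
    ind = pm.indicators[clinical.sample_ids]
    times = clinical.os_time
    events = clinical.os_event
    hits: list[tuple[str, CoxFit]] = []
    n_unidentifiable = 0
    n_nonconverged = 0
    for pair_id, row in zip(ind.index, ind.to_numpy(dtype=float)):
        fit = cox_fit(times, events, row[:, None], names=[pair_id], ties=ties)
        if fit.k == 0:
            n_unidentifiable += 1
            continue
        if not fit.converged:
            n_nonconverged += 1
            continue
        if fit.p[0] < p_max:
            hits.append((pair_id, fit))
    hits.sort(key=lambda t: t[1].p[0])
    report = {
        "n_tested": pm.n_pairs,
        "n_retained": len(hits),
        "n_unidentifiable": n_unidentifiable,
        "n_nonconverged": n_nonconverged,
    }
    return hits, report


def stepwise_cox(times, events, X_candidates, names=None, ties: str = "efron") -> CoxFit:
    """Forward stepwise Cox selection by AIC with backward refinement.

    Starting from the empty model, the candidate whose inclusion most lowers
    AIC is added; after each addition single-covariate removals that lower
    AIC are applied; the search stops when no move improves AIC. When nothing
    beats the null model the null fit (no covariates) is returned.
    """
    X = np.asarray(X_candidates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if X.shape[1] == 0:
        raise ValueError("need at least one candidate")

    def fit_subset(idx: list[int]) -> CoxFit:
        if not idx:
            return cox_fit(times, events, np.empty((X.shape[0], 0)), names=[], ties=ties)
        return cox_fit(times, events, X[:, idx], names=[names[i] for i in idx], ties=ties)

    current: list[int] = []
    best = fit_subset(current)
    improved = True
    while improved:
        improved = False
        # forward: best single addition
        best_add, best_add_fit = None, None
        for j in range(X.shape[1]):
            if j in current:
                continue
            cand = fit_subset(current + [j])
            if cand.monotone_likelihood or not cand.converged:
                continue
            if cand.k != len(current) + 1:  # candidate dropped as collinear/constant
                continue
            if cand.aic < best.aic - 1e-10 and (best_add_fit is None or cand.aic < best_add_fit.aic):
                best_add, best_add_fit = j, cand
        if best_add is not None:
            current.append(best_add)
            best = best_add_fit
            improved = True
            # backward refinement
            removed = True
            while removed and len(current) > 1:
                removed = False
                for j in list(current):
                    trial = fit_subset([i for i in current if i != j])
                    if trial.converged and trial.aic < best.aic - 1e-10:
                        current.remove(j)
                        best = trial
                        removed = True
                        break
    return best
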