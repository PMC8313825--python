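"""L1-penalized Cox regression with cross-validated lambda selection.

The regularization path is solved by glmnet-style coordinate descent
(scikit-survival's coxnet) over a 100-point log-spaced lambda grid from
lambda_max (smallest lambda whose solution is all-zero) down to
0.01*lambda_max. Columns are standardized internally; coefficients are
reported on the original covariate scale. Cross-validation scores each
lambda by the Verweij-van Houwelingen partial-likelihood deviance
  dev_k(lambda) = -2 * ( l_full(beta_-k) - l_train(beta_-k) ),
with folds stratified by the event indicator; both the deviance-minimizing
lambda_min and the one-standard-error lambda_1se are recorded, and selection
uses lambda_min by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .coxph import cox_loglik

__all__ = ["LassoCoxFit", "lasso_cox", "fit_path"]


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, sd_safe


def fit_path(times, events, X, alphas=None, n_alphas: int = 100,
             alpha_min_ratio: float = 0.01, tol: float = 1e-9):
    """Solve the L1 Cox path; returns (alphas, coef_path) on the original scale.

    ``coef_path`` has shape (p, n_alphas). Standardization happens here; the
    penalty applies on the standardized scale (glmnet convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    Xs, sd = _standardize(X)
    y = Surv.from_arrays(event=events.astype(bool), time=times)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=alphas,
        n_alphas=n_alphas,
        alpha_min_ratio=alpha_min_ratio,
        normalize=False,
        tol=tol,
        max_iter=200000,
        fit_baseline_model=False,
    )
    model.fit(Xs, y)
    coef_std = model.coef_  # (p, n_alphas)
    coef_orig = coef_std / sd[:, None]
    return np.asarray(model.alphas_), coef_orig, coef_std, sd


@dataclass
class LassoCoxFit:
    """LASSO-Cox path with cross-validated lambda choice."""

    names: list[str]
    alphas: np.ndarray            # lambda grid, decreasing
    coef_path: np.ndarray         # (p, n_lambda), original covariate scale
    cv_deviance: np.ndarray       # mean fold deviance per lambda
    cv_deviance_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    seed: int
    lambda_rule: str = "lambda_min"

    @property
    def chosen_lambda(self) -> float:
        return self.lambda_min if self.lambda_rule == "lambda_min" else self.lambda_1se

    def coef_at(self, lam: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.alphas - lam)))
        return self.coef_path[:, idx]

    @property
    def selected(self) -> list[str]:
        coef = self.coef_at(self.chosen_lambda)
        return [nm for nm, c in zip(self.names, coef) if c != 0.0]

    @property
    def n_nonzero_path(self) -> np.ndarray:
        return (self.coef_path != 0).sum(axis=0)


def lasso_cox(times, events, X, names=None, n_folds: int = 10, seed: int = 0,
              lambda_rule: str = "lambda_min", n_alphas: int = 100,
              alpha_min_ratio: float = 0.01) -> LassoCoxFit:
    """Cross-validated LASSO Cox fit.

    Folds are stratified by the event indicator so events stay balanced; the
    fold scheme needs at least ``n_folds`` events (and censorings, when any
    exist) — otherwise an error suggests lowering ``n_folds``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if len(times) < n_folds:
        raise ValueError("n >= n_folds required")
    if events.sum() < n_folds:
        raise ValueError(
            f"only {int(events.sum())} events for {n_folds} folds; lower n_folds"
        )

    alphas, coef_path, _, _ = fit_path(
        times, events, X, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio
    )

    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_dev = np.full((n_folds, alphas.size), np.nan)
    ll_full_cache: dict[int, float] = {}
    for k, (train_idx, _) in enumerate(splitter.split(X, events)):
        try:
            a_k, coef_k, _, _ = fit_path(
                times[train_idx], events[train_idx], X[train_idx], alphas=list(alphas)
            )
        except (ValueError, ArithmeticError):
            continue
        for j in range(a_k.size):
            beta = coef_k[:, j]
            ll_full = cox_loglik(beta, times, events, X, ties="breslow")
            ll_train = cox_loglik(beta, times[train_idx], events[train_idx], X[train_idx], ties="breslow")
            fold_dev[k, j] = -2.0 * (ll_full - ll_train)
    valid = ~np.all(np.isnan(fold_dev), axis=0)
    mean_dev = np.nanmean(fold_dev, axis=0)
    with np.errstate(invalid="ignore"):
        se_dev = np.nanstd(fold_dev, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(fold_dev), axis=0).clip(min=1)
        )
    mean_masked = np.where(valid, mean_dev, np.inf)
    i_min = int(np.argmin(mean_masked))
    lambda_min = float(alphas[i_min])
    thresh = mean_dev[i_min] + se_dev[i_min]
    within = np.where(valid & (mean_dev <= thresh))[0]
    lambda_1se = float(alphas[within.min()]) if within.size else lambda_min  # alphas decreasing

    return LassoCoxFit(
        names=names,
        alphas=alphas,
        coef_path=coef_path,
        cv_deviance=mean_dev,
        cv_deviance_se=se_dev,
        lambda_min=lambda_min,
        lambda_1se=lambda_1se,
        seed=seed,
        lambda_rule=lambda_rule,
    )
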