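import numpy as np
import pandas as pd
import pytest

from lncpair.coxph import (
    cox_fit,
    cox_loglik,
    km_estimate,
    logrank_test,
    stepwise_cox,
    univariate_pair_screen,
)
from lncpair.io import ClinicalTable
from lncpair.pairing import PairMatrix

from conftest import random_survival


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # subjects: t=1 event, t=2 censored, t=3 event
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2.0 / 3.0)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_reduces_to_empirical_survival(self, rng):
        t = rng.exponential(10, 50) + 0.01
        km = km_estimate(t, np.ones(50, dtype=int))
        for q in [0.2, 0.5, 0.9]:
            tq = np.quantile(t, q)
            assert km.survival_at(tq) == pytest.approx((t > tq).mean(), abs=1e-12)

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([1.0, 5.0, 9.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(7.0) == pytest.approx(1.0)

    def test_monotone_and_bounded(self, rng):
        t, e, _ = random_survival(rng, 200)
        km = km_estimate(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


def hand_logrank(times, events, group):
    """From-scratch hypergeometric table computation (independent oracle)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    O_E, V = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        O_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_E**2 / V


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computable_six_subjects(self):
        t = [2.0, 4.0, 5.0, 3.0, 6.0, 7.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(hand_logrank(t, e, g), abs=1e-12)

    def test_power_against_rate_ratio_three(self):
        hits = 0
        rng = np.random.default_rng(77)
        for _ in range(100):
            t0 = rng.exponential(1.0, 200)
            t1 = rng.exponential(1.0 / 3.0, 200)
            t = np.concatenate([t0, t1]) + 1e-9
            e = np.ones(400, dtype=int)
            g = np.concatenate([np.zeros(200, int), np.ones(200, int)])
            _, p = logrank_test(t, e, g)
            hits += p < 0.001
        assert hits >= 99

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t, e, _ = random_survival(rng, 120)
        g = (rng.random(120) < 0.5).astype(int)
        chi2, p = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


def hand_cox_loglik_breslow(beta, times, events, x):
    """O(n^2) direct Breslow partial likelihood for a single covariate."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCoxFit:
    def test_antisymmetry_of_binary_relabel(self, rng):
        t, e, _ = random_survival(rng, 100)
        x = (rng.random(100) < 0.5).astype(float)
        f1 = cox_fit(t, e, x)
        f2 = cox_fit(t, e, 1.0 - x)
        assert f1.beta[0] == pytest.approx(-f2.beta[0], abs=1e-8)

    def test_grid_search_oracle_eight_subjects(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        fit = cox_fit(t, e, x, ties="breslow")
        grid = np.arange(-4, 4, 1e-4)
        lls = [hand_cox_loglik_breslow(b, t, e, x) for b in grid]
        b_star = grid[int(np.argmax(lls))]
        assert fit.beta[0] == pytest.approx(b_star, abs=1e-3)

    def test_loglik_is_local_maximum(self, rng):
        t, e, x = random_survival(rng, 80, beta=0.7)
        fit = cox_fit(t, e, x)
        ll_hat = cox_loglik(fit.beta, t, e, x)
        for delta in (-0.05, 0.05):
            assert cox_loglik(fit.beta + delta, t, e, x) <= ll_hat + 1e-12

    def test_separation_flagged_as_monotone_likelihood(self):
        t = np.arange(1.0, 11.0)
        e = np.ones(10, dtype=int)
        x = (t > 5).astype(float)  # perfectly orders event times
        fit = cox_fit(t, e, x)
        assert fit.monotone_likelihood and not fit.converged

    def test_constant_covariate_dropped_with_report(self, rng):
        t, e, x = random_survival(rng, 50, beta=0.5)
        X = np.column_stack([x, np.ones(50)])
        fit = cox_fit(t, e, X, names=["x", "const"])
        assert fit.names == ["x"] and fit.dropped == ["const"]

    def test_efron_equals_breslow_without_ties(self, rng):
        for _ in range(5):
            t, e, x = random_survival(rng, 60, beta=0.4)
            fe = cox_fit(t, e, x, ties="efron")
            fb = cox_fit(t, e, x, ties="breslow")
            assert fe.beta[0] == pytest.approx(fb.beta[0], abs=1e-9)
            assert fe.loglik == pytest.approx(fb.loglik, abs=1e-9)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        t = np.ceil(rng.exponential(20, 150))  # heavy ties
        e = rng.integers(0, 2, 150)
        X = rng.standard_normal((150, 2))
        t = t * np.exp(-0.3 * X[:, 0])
        fit = cox_fit(t, e, X, names=["a", "b"])
        df = pd.DataFrame(X, columns=["a", "b"]).assign(t=t, e=e)
        ref = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.beta, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-5)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-7)

    def test_hr_ci_aic_consistency(self, rng):
        t, e, x = random_survival(rng, 120, beta=0.8)
        fit = cox_fit(t, e, x)
        assert fit.hr[0] == pytest.approx(np.exp(fit.beta[0]))
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        lo, hi = fit.ci95[0]
        assert lo < fit.hr[0] < hi

    def test_too_many_covariates_rejected(self, rng):
        t, e, _ = random_survival(rng, 5)
        with pytest.raises(ValueError):
            cox_fit(t, e, rng.standard_normal((5, 6)))


class TestUnivariatePairScreen:
    def _pm_clinical(self, rng, n=300, beta=1.0, n_noise=5):
        c = (rng.random(n) < 0.5).astype(int)
        t = rng.exponential(100, n) / np.exp(beta * c) + 1e-6
        e = np.ones(n, dtype=int)
        samples = [f"P{i}" for i in range(n)]
        rows = {"A|B": c}
        for j in range(n_noise):
            rows[f"N{j}|M{j}"] = (rng.random(n) < 0.5).astype(int)
        pm = PairMatrix(pd.DataFrame(rows, index=samples).T)
        cl = ClinicalTable(pd.DataFrame({"os_time": t, "os_event": e}, index=samples))
        return pm, cl

    def test_planted_pair_retained(self, rng):
        pm, cl = self._pm_clinical(rng)
        hits, report = univariate_pair_screen(pm, cl)
        assert "A|B" in [pid for pid, _ in hits]
        assert report["n_tested"] == 6

    def test_degenerate_threshold_empties(self, rng):
        pm, cl = self._pm_clinical(rng)
        hits, _ = univariate_pair_screen(pm, cl, p_max=0.0)
        assert hits == []

    def test_alignment_mismatch_names_samples(self, rng):
        pm, cl = self._pm_clinical(rng, n=10)
        pm2 = PairMatrix(pm.indicators.rename(columns={"P0": "ZZ"}))
        with pytest.raises(ValueError, match="ZZ"):
            univariate_pair_screen(pm2, cl)

    def test_null_pairs_type_one_error_controlled(self):
        rng = np.random.default_rng(5)
        n, n_pairs = 150, 200
        t = rng.exponential(50, n) + 1e-6
        e = np.ones(n, dtype=int)
        samples = [f"P{i}" for i in range(n)]
        rows = {f"A{j}|B{j}": (rng.random(n) < 0.5).astype(int) for j in range(n_pairs)}
        pm = PairMatrix(pd.DataFrame(rows, index=samples).T)
        cl = ClinicalTable(pd.DataFrame({"os_time": t, "os_event": e}, index=samples))
        hits, _ = univariate_pair_screen(pm, cl, p_max=0.05)
        assert 0.02 * n_pairs <= len(hits) <= 0.09 * n_pairs


class TestStepwise:
    def test_single_informative_candidate_selected(self, rng):
        x = (rng.random(300) < 0.5).astype(float)
        t = rng.exponential(100, 300) / np.exp(1.0 * x) + 1e-6
        fit = stepwise_cox(t, np.ones(300, int), x[:, None], names=["pair"])
        assert fit.names == ["pair"]

    def test_duplicated_covariate_enters_once(self, rng):
        x = (rng.random(300) < 0.5).astype(float)
        t = rng.exponential(100, 300) / np.exp(1.0 * x) + 1e-6
        X = np.column_stack([x, x])
        fit = stepwise_cox(t, np.ones(300, int), X, names=["p1", "p2"])
        assert fit.k == 1

    @pytest.mark.parametrize(
        "n_cand,band",
        [
            # AIC admits a null candidate when its LR statistic exceeds 2, i.e.
            # with probability P(chi2_1 > 2) ~ 0.157 per independent candidate;
            # bands are 3-sigma binomial intervals around (1 - 0.157)^k over
            # 100 replicates
            (1, (73, 95)),
            (4, (36, 66)),
        ],
    )
    def test_pure_noise_empty_model_rate_matches_chi2_null(self, n_cand, band):
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = rng.exponential(50, 100) + 1e-6
            X = (rng.random((100, n_cand)) < 0.5).astype(float)
            fit = stepwise_cox(t, np.ones(100, int), X)
            empty += fit.k == 0
        assert band[0] <= empty <= band[1]
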