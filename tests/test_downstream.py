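import numpy as np
import pandas as pd
import pytest

from lncpair.downstream import (
    DrugResponseTable,
    InfiltrationTable,
    clinical_association,
    drug_sensitivity_compare,
    encode_ordinal,
    group_expression_compare,
    immune_correlation,
    independence_cox,
    rank_sum_test,
)
from lncpair.io import ClinicalTable, ExpressionMatrix
from lncpair.signature import stratify

from conftest import random_survival


def _profile(scores, cutoff=None):
    s = pd.Series(scores, index=[f"P{i}" for i in range(len(scores))])
    return stratify(s, float(np.median(s)) if cutoff is None else cutoff)


def _clinical(n, rng, **cols):
    data = {"os_time": rng.exponential(100, n) + 1, "os_event": rng.integers(0, 2, n)}
    data.update(cols)
    return ClinicalTable(pd.DataFrame(data, index=[f"P{i}" for i in range(n)]))


def chi2_2x2_closed_form(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def chi2_from_oe(table):
    table = np.asarray(table, float)
    E = np.outer(table.sum(1), table.sum(0)) / table.sum()
    return ((table - E) ** 2 / E).sum()


class TestClinicalAssociation:
    def test_chi2_matches_closed_form_2x2(self, rng):
        # risk group x feature counts [[10,20],[20,10]]
        groups = ["high"] * 30 + ["low"] * 30
        feature = ["A"] * 10 + ["B"] * 20 + ["A"] * 20 + ["B"] * 10
        scores = pd.Series(
            np.where(np.array(groups) == "high", 1.0, 0.0) + rng.normal(0, 0.01, 60),
            index=[f"P{i}" for i in range(60)],
        )
        profile = stratify(scores, 0.5)
        cl = _clinical(60, rng, feat=feature)
        res = clinical_association(profile, cl, features=["feat"])
        chi2 = [r for r in res if r.test == "chi_squared"][0]
        assert chi2.statistic == pytest.approx(chi2_2x2_closed_form(10, 20, 20, 10))
        assert chi2.statistic == pytest.approx(chi2_from_oe([[10, 20], [20, 10]]))

    def test_exchangeable_categories_give_large_wilcoxon_p(self, rng):
        scores = np.tile(rng.standard_normal(30), 2)
        feature = ["A"] * 30 + ["B"] * 30
        profile = _profile(scores)
        cl = _clinical(60, rng, feat=feature)
        res = clinical_association(profile, cl, features=["feat"])
        wil = [r for r in res if r.test == "wilcoxon_rank_sum"][0]
        assert wil.p > 0.9

    def test_three_categories_use_kruskal(self, rng):
        profile = _profile(rng.standard_normal(90))
        cl = _clinical(90, rng, feat=list("ABC") * 30)
        res = clinical_association(profile, cl, features=["feat"])
        assert any(r.test == "kruskal_wallis" for r in res)

    def test_type_one_error_near_nominal(self):
        rejections, n_rep = 0, 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            profile = _profile(rng.standard_normal(400))
            cl = _clinical(400, rng, feat=rng.choice(list("AB"), 400))
            res = clinical_association(profile, cl, features=["feat"])
            chi2 = [r for r in res if r.test == "chi_squared"][0]
            rejections += chi2.p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_p_invariant_to_sample_order(self, rng):
        scores = rng.standard_normal(50)
        feat = rng.choice(list("AB"), 50)
        profile = _profile(scores)
        cl = _clinical(50, rng, feat=feat)
        res1 = clinical_association(profile, cl, features=["feat"])
        perm = rng.permutation(50)
        profile2 = stratify(profile.scores.iloc[perm], profile.cutoff)
        cl2 = ClinicalTable(cl.data.iloc[perm])
        res2 = clinical_association(profile2, cl2, features=["feat"])
        for r1, r2 in zip(res1, res2):
            assert r1.p == pytest.approx(r2.p, abs=1e-12)


class TestRankSum:
    def test_invariant_under_increasing_transform(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(25) + 0.5
        _, p1 = rank_sum_test(x, y)
        _, p2 = rank_sum_test(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_exact_small_sample_branch(self):
        x = np.array([1.0, 3.0, 5.0])
        y = np.array([2.0, 4.0, 6.0])
        from scipy.stats import mannwhitneyu

        stat, p = rank_sum_test(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)


class TestIndependenceCox:
    def test_duplicate_covariate_triggers_collinearity_drop(self, rng):
        t, e, x = random_survival(rng, 100, beta=0.5)
        scores = pd.Series(x, index=[f"P{i}" for i in range(100)])
        cl = ClinicalTable(pd.DataFrame(
            {"os_time": t, "os_event": e, "dup": x}, index=scores.index))
        uni, multi = independence_cox(scores, cl)
        assert "dup" in multi.dropped
        assert multi.names == ["risk_score"]

    def test_wald_p_invariant_to_linear_rescaling(self, rng):
        t, e, x = random_survival(rng, 150, beta=0.7)
        idx = [f"P{i}" for i in range(150)]
        age = rng.normal(60, 10, 150)
        cl1 = ClinicalTable(pd.DataFrame({"os_time": t, "os_event": e, "age": age}, index=idx))
        cl2 = ClinicalTable(pd.DataFrame(
            {"os_time": t, "os_event": e, "age": (age - 60) / 10}, index=idx))
        s = pd.Series(x, index=idx)
        _, m1 = independence_cox(s, cl1)
        _, m2 = independence_cox(s, cl2)
        np.testing.assert_allclose(m1.p, m2.p, atol=1e-8)

    def test_score_prognostic_stage_not_when_only_eta_drives_hazard(self):
        wins = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 300
            eta = rng.standard_normal(n)
            stage_latent = 0.2 * eta + np.sqrt(1 - 0.04) * rng.standard_normal(n)
            stage = np.digitize(stage_latent, np.quantile(stage_latent, [0.25, 0.5, 0.75])) + 1
            t = rng.exponential(100, n) / np.exp(eta) + 1e-6
            idx = [f"P{i}" for i in range(n)]
            cl = ClinicalTable(pd.DataFrame(
                {"os_time": t, "os_event": np.ones(n, int), "stage_num": stage}, index=idx))
            _, multi = independence_cox(pd.Series(eta, index=idx), cl)
            summ = multi.summary()
            ok = summ.loc["risk_score", "p"] < 0.05 and summ.loc["stage_num", "p"] > 0.05
            wins += ok
        assert wins >= 0.8 * n_rep

    def test_ordinal_encoding_defaults(self, rng):
        cl = _clinical(4, rng, stage=["I", "II", "III", "IV"], T=["T1", "T2", "T3", "T4"])
        enc = encode_ordinal(cl)
        assert enc["stage"].tolist() == [1.0, 2.0, 3.0, 4.0]
        assert enc["T"].tolist() == [1.0, 2.0, 3.0, 4.0]


class TestImmuneCorrelation:
    def _infil(self, scores, transform):
        return InfiltrationTable(pd.DataFrame({
            "sample_id": scores.index, "cell_type": "CD8_T_cell",
            "method": "simulated", "score": transform(scores.to_numpy())}))

    def test_exact_negative_monotone_gives_rho_minus_one(self, rng):
        profile = _profile(rng.standard_normal(40))
        infil = self._infil(profile.scores, lambda s: -s)
        res = immune_correlation(profile, infil)
        rho = [r for r in res if r.test == "spearman"][0]
        assert rho.statistic == pytest.approx(-1.0)
        assert rho.direction == "negative"

    def test_constant_column_skipped(self, rng):
        profile = _profile(rng.standard_normal(40))
        infil = self._infil(profile.scores, lambda s: np.zeros_like(s))
        assert immune_correlation(profile, infil) == []

    def test_permuted_scores_near_zero_rho(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            profile = _profile(rng.standard_normal(500))
            infil = self._infil(profile.scores, lambda s: rng.permutation(s))
            res = immune_correlation(profile, infil)
            rho = [r for r in res if r.test == "spearman"][0]
            hits += abs(rho.statistic) < 0.15
        assert hits >= 19


class TestGroupExpression:
    def _expr(self, rows, samples):
        return ExpressionMatrix(pd.DataFrame(rows, index=samples).T)

    def test_identical_distribution_not_significant(self, rng):
        profile = _profile(np.arange(40, dtype=float))
        vals = np.tile(rng.exponential(2, 20), 2)
        order = np.argsort(np.argsort(profile.scores.to_numpy()))
        expr = self._expr({"CTLA4": vals[order]}, list(profile.scores.index))
        res = group_expression_compare(expr, profile, ["CTLA4"])
        assert res[0].p > 0.9

    def test_shifted_gene_detected_with_direction(self, rng):
        n = 500
        profile = _profile(rng.standard_normal(n))
        logx = rng.normal(5, 1, n)
        hi = np.isin(profile.scores.index, profile.high_samples)
        logx[hi] -= 1.0
        expr = self._expr({"PDCD1": np.exp2(logx) - 1}, list(profile.scores.index))
        res = group_expression_compare(expr, profile, ["PDCD1"])
        assert res[0].p < 0.001 and res[0].direction == "lower in high"

    def test_empty_and_missing_genes_reported_not_fatal(self, rng):
        profile = _profile(rng.standard_normal(10))
        expr = self._expr({"G1": rng.exponential(1, 10)}, list(profile.scores.index))
        assert group_expression_compare(expr, profile, []) == []
        res = group_expression_compare(expr, profile, ["NOPE"])
        assert res[0].test == "missing"


class TestDrugSensitivity:
    def _drugs(self, scores, gammas, rng):
        z = (scores - scores.mean()) / scores.std()
        rows = []
        for drug, g in gammas.items():
            ic50 = np.exp(g * z + 0.1 * rng.standard_normal(len(z)))
            rows.append(pd.DataFrame({"sample_id": scores.index, "drug": drug, "ic50": ic50}))
        return DrugResponseTable(pd.concat(rows, ignore_index=True))

    def test_opposite_gammas_report_opposite_directions(self, rng):
        profile = _profile(rng.standard_normal(300))
        drugs = self._drugs(profile.scores, {"mtx": -1.0, "doc": 1.0}, rng)
        res = {r.feature: r for r in drug_sensitivity_compare(profile, drugs)}
        assert res["mtx"].direction == "lower in high" and res["mtx"].significant
        assert res["doc"].direction == "higher in high" and res["doc"].significant

    def test_null_drug_not_significant(self, rng):
        profile = _profile(np.arange(60, dtype=float))
        ic50 = np.tile(rng.exponential(1, 30), 2)
        order = np.argsort(np.argsort(profile.scores.to_numpy()))
        drugs = DrugResponseTable(pd.DataFrame(
            {"sample_id": profile.scores.index, "drug": "cis", "ic50": ic50[order]}))
        res = drug_sensitivity_compare(profile, drugs)
        assert not res[0].significant
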