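import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from tmepipe.io_core import ClinicalTable, ValidationError
from tmepipe.survival import (
    cell_network,
    cox_fit,
    delong_compare,
    km_fit,
    logrank_test,
    logrank_z,
    logrank_z_cuts,
    roc_auc,
)


def brute_force_logrank(time, event, groups):
    """Independent risk-set arithmetic for the two-group log-rank chi-square."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups, int)
    O = E = V = 0.0
    for et in sorted(set(time[event == 1])):
        at_risk = time >= et
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((time == et) & (event == 1)).sum()
        d1 = ((time == et) & (event == 1) & (groups == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKMLogrank:
    def test_km_single_group_matches_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.ones(5, int)
        curve = km_fit(t, e)[0]
        np.testing.assert_allclose(curve.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [5, 4, 3, 2, 1])

    def test_km_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        e = rng.binomial(1, 0.7, 50)
        curve = km_fit(t, e)[0]
        kmf = KaplanMeierFitter().fit(t, e)
        ours = pd.Series(curve.survival, index=curve.times)
        theirs = kmf.survival_function_["KM_estimate"]
        for et, s in ours.items():
            assert s == pytest.approx(theirs.loc[et], abs=1e-12)

    def test_textbook_two_group_fixture_equals_risk_set_arithmetic(self):
        t = np.array([6, 7, 10, 15, 19, 25, 1, 3, 5, 8, 12, 17], float)
        e = np.ones(12, int)
        g = np.array([0] * 6 + [1] * 6)
        chi2, df, p = logrank_test(t, e, g)
        assert df == 1
        assert chi2 == pytest.approx(brute_force_logrank(t, e, g), abs=1e-10)
        r = lifelines_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(r.test_statistic, abs=1e-8)

    def test_identical_groups_give_null_statistic(self):
        t = np.tile(np.arange(1.0, 11.0), 2)
        e = np.ones(20, int)
        g = np.repeat([0, 1], 10)
        chi2, _, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p > 0.99

    def test_three_group_logrank_df(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 60)
        e = np.ones(60, int)
        g = np.repeat([0, 1, 2], 20)
        chi2, df, p = logrank_test(t, e, g)
        assert df == 2
        assert 0 <= p <= 1

    def test_logrank_p_uniform_under_null_permutation(self):
        """Random splits of one homogeneous sample calibrate near uniform."""
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 40)
        e = np.ones(40, int)
        ps = []
        for _ in range(300):
            g = rng.permutation(np.repeat([0, 1], 20))
            ps.append(logrank_test(t, e, g)[2])
        ps = np.array(ps)
        assert 0.01 <= (ps < 0.05).mean() <= 0.10
        assert abs(ps.mean() - 0.5) < 0.08

    def test_vectorized_cut_statistics_equal_scalar_path(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 30)
        e = rng.binomial(1, 0.8, 30)
        score = rng.normal(0, 1, 30)
        cands = np.quantile(score, [0.2, 0.4, 0.6, 0.8])
        vec = logrank_z_cuts(t, e, score, cands)
        for c, z in zip(cands, vec):
            assert z == pytest.approx(logrank_z(t, e, score > c), abs=1e-12)


class TestCox:
    def test_null_covariate_small_z(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 300)
        e = np.ones(300, int)
        x = rng.normal(0, 1, 300)
        fit = cox_fit(t, e, x[:, None])
        assert abs(fit.coef[0]) < 0.15
        assert abs(fit.z[0]) < 2.5

    def test_true_hazard_ratio_recovered(self):
        rng = np.random.default_rng(4)
        x = rng.binomial(1, 0.5, 500).astype(float)
        t = rng.exponential(1 / np.exp(np.log(2) * x))
        e = np.ones(500, int)
        fit = cox_fit(t, e, x[:, None])
        assert 1.7 <= fit.hr[0] <= 2.3
        assert fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]
        assert np.exp(fit.coef[0]) == pytest.approx(fit.hr[0])

    def test_matches_lifelines_coefficients(self):
        rng = np.random.default_rng(6)
        n = 150
        X = rng.normal(0, 1, (n, 2))
        t = rng.exponential(1 / np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1]))
        e = rng.binomial(1, 0.8, n)
        fit = cox_fit(t, e, X)
        df = pd.DataFrame({"T": t, "E": e, "x0": X[:, 0], "x1": X[:, 1]})
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_score_test_equals_logrank_chi2(self):
        """Classical identity (Breslow, no tied event times)."""
        rng = np.random.default_rng(8)
        x = rng.binomial(1, 0.4, 80).astype(float)
        t = rng.exponential(1 / np.exp(0.8 * x))
        e = rng.binomial(1, 0.85, 80)
        fit = cox_fit(t, e, x[:, None])
        chi2, _, _ = logrank_test(t, e, x.astype(int))
        assert fit.score_chi2_null == pytest.approx(chi2, abs=1e-6)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 50)
        t = rng.exponential(1, 50)
        e = np.ones(50, int)
        with pytest.raises(ValidationError, match="singular"):
            cox_fit(t, e, np.c_[x, x])

    def test_perfect_separation_flagged_not_fatal(self, caplog):
        t = np.concatenate([np.arange(1, 21), np.arange(100, 120)]).astype(float)
        e = np.ones(40, int)
        x = np.repeat([1.0, 0.0], 20)
        with caplog.at_level("WARNING", logger="tmepipe"):
            fit = cox_fit(t, e, x[:, None], max_iter=25)
        assert not fit.converged


class TestCellNetwork:
    def test_planted_driver_has_largest_impact_with_risk_sign(self):
        rng = np.random.default_rng(10)
        n = 200
        fr = pd.DataFrame(
            rng.dirichlet(np.ones(4), n), columns=list("ABCD"),
            index=[f"s{i}" for i in range(n)])
        lam = 0.01 * np.exp(3 * (fr["A"] > fr["A"].median()))
        t = rng.exponential(1 / lam)
        clin = ClinicalTable(pd.DataFrame(
            {"os_time": t, "os_event": np.ones(n, int)}, index=fr.index))
        net = cell_network(fr, clin)
        assert net.impact["impact"].idxmax() == "A"
        assert net.impact.loc["A", "direction"] == "risk"

    def test_duplicated_cell_type_yields_perfect_edge(self):
        rng = np.random.default_rng(11)
        fr = pd.DataFrame({"A": rng.random(60)})
        fr["B"] = fr["A"]
        fr["C"] = rng.random(60)
        fr.index = [f"s{i}" for i in range(60)]
        clin = ClinicalTable(pd.DataFrame(
            {"os_time": rng.exponential(5, 60), "os_event": np.ones(60, int)},
            index=fr.index))
        net = cell_network(fr, clin)
        ab = net.edges[(net.edges["a"] == "A") & (net.edges["b"] == "B")]
        assert len(ab) == 1 and ab["rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(12)
        fr = pd.DataFrame({"A": rng.random(40), "B": np.full(40, 0.5)},
                          index=[f"s{i}" for i in range(40)])
        clin = ClinicalTable(pd.DataFrame(
            {"os_time": rng.exponential(5, 40), "os_event": np.ones(40, int)},
            index=fr.index))
        with caplog.at_level("WARNING", logger="tmepipe"):
            net = cell_network(fr, clin)
        assert "B" not in net.impact.index
        assert len(net.edges) == 0


class TestROC:
    def test_perfect_separation_auc_one(self):
        s = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert roc_auc(s, y) == 1.0

    def test_independent_score_auc_near_half(self):
        rng = np.random.default_rng(13)
        s = rng.normal(0, 1, 4000)
        y = rng.binomial(1, 0.5, 4000)
        assert roc_auc(s, y) == pytest.approx(0.5, abs=0.03)

    def test_six_point_hand_example_equals_pair_enumeration(self):
        s = np.array([3.0, 1.0, 2.0, 5.0, 4.0, 2.0])
        y = np.array([1, 0, 0, 1, 1, 0])
        conc = 0.0
        npairs = 0
        for i in range(6):
            for j in range(6):
                if y[i] == 1 and y[j] == 0:
                    npairs += 1
                    conc += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert roc_auc(s, y) == pytest.approx(conc / npairs)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        s = rng.normal(0, 1, 200)
        y = rng.binomial(1, 0.4, 200)
        assert roc_auc(s, y) == pytest.approx(roc_auc(np.exp(s), y))
        assert roc_auc(s, y) == pytest.approx(roc_auc(2 * s - 7, y))

    def test_delong_identical_scores_no_difference(self):
        rng = np.random.default_rng(15)
        s = rng.normal(0, 1, 100)
        y = rng.binomial(1, 0.5, 100)
        d, z, p = delong_compare(s, s.copy(), y)
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_delong_detects_a_real_difference(self):
        rng = np.random.default_rng(16)
        n = 400
        y = rng.binomial(1, 0.5, n)
        good = y + rng.normal(0, 0.5, n)
        bad = rng.normal(0, 1, n)
        d, z, p = delong_compare(good, bad, y)
        assert d > 0.2
        assert p < 1e-6

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.arange(5.0), np.ones(5, int))
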