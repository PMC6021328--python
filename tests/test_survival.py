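import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from gapstrat.survival import (
    Covariate,
    SurvivalError,
    apply_inclusion_filter,
    cox_fit,
    km_by_group,
    km_fit,
    km_median,
    logrank_pairwise,
    logrank_test,
    stepwise_cox,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def logrank_oracle_2group(t1, e1, t2, e2):
    """Brute-force 2-group log-rank: a 2x2 table at every distinct event time."""
    all_t = sorted(set([t for t, e in zip(t1, e1) if e == 1]
                       + [t for t, e in zip(t2, e2) if e == 1]))
    O1 = E1 = V = 0.0
    for u in all_t:
        n1 = sum(1 for t in t1 if t >= u)
        n2 = sum(1 for t in t2 if t >= u)
        d1 = sum(1 for t, e in zip(t1, e1) if t == u and e == 1)
        d2 = sum(1 for t, e in zip(t2, e2) if t == u and e == 1)
        n, d = n1 + n2, d1 + d2
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    stat = (O1 - E1) ** 2 / V if V > 0 else 0.0
    return stat


# ---------------------------------------------------------------------------
# inclusion filter
# ---------------------------------------------------------------------------

class TestInclusionFilter:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["id", "os_months", "event"])

    def test_death_at_two_included(self):
        df = self.make([("a", 2, 1)])
        inc, exc = apply_inclusion_filter(df)
        assert len(inc) == 1 and len(exc) == 0

    def test_death_within_first_month_excluded(self):
        df = self.make([("a", 1, 1), ("b", 0, 1)])
        inc, exc = apply_inclusion_filter(df)
        assert len(inc) == 0
        assert list(exc["exclusion_reason"]) == ["early_death", "early_death"]

    def test_alive_at_17_excluded(self):
        df = self.make([("a", 17, 0), ("b", 18, 0)])
        inc, exc = apply_inclusion_filter(df)
        assert list(inc["id"]) == ["b"]
        assert list(exc["exclusion_reason"]) == ["short_followup"]

    def test_missing_os_routed_with_reason(self):
        df = self.make([("a", None, 1)])
        inc, exc = apply_inclusion_filter(df)
        assert len(inc) == 0
        assert list(exc["exclusion_reason"]) == ["missing_os"]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_single_death(self):
        curve = km_fit([5], [1])
        assert km_median(curve) == 5

    def test_product_limit_by_hand(self):
        # events at 1,2,3,4, no censoring: S(2) = 0.5 exactly
        curve = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert km_median(curve) == 2

    def test_all_censored_median_not_reached(self):
        curve = km_fit([5, 8, 9], [0, 0, 0])
        assert km_median(curve) is None
        assert curve.n_events == 0

    def test_no_censoring_matches_empirical_survivor(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 40, size=60).astype(float)
        curve = km_fit(t, np.ones_like(t))
        for u in np.unique(t):
            assert curve.survival_at(u) == pytest.approx((t > u).mean())

    def test_matches_lifelines(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 200).round() + 1
        e = (rng.random(200) < 0.7).astype(int)
        curve = km_fit(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u in curve.times:
            assert curve.survival_at(u) == pytest.approx(
                float(kmf.survival_function_at_times(u).iloc[0]))

    def test_median_convention_smallest_t_at_half(self):
        # S drops exactly to 0.5 at t=7 and stays: median must be 7
        curve = km_fit([7, 7, 9, 11], [1, 1, 0, 0])
        assert curve.survival_at(7) == pytest.approx(0.5)
        assert km_median(curve) == 7

    def test_empty_input_errors(self):
        with pytest.raises(SurvivalError):
            km_fit([], [])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([3, 5, 8, 12], [1, 1, 0, 1])
        res = logrank_test([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_permutation_symmetric(self):
        a = ([2, 4, 9], [1, 1, 1])
        b = ([5, 7, 11, 13], [1, 0, 1, 1])
        assert logrank_test([a, b]).statistic == pytest.approx(
            logrank_test([b, a]).statistic)

    def test_hand_worked_six_subjects_vs_oracle(self):
        t1, e1 = [1, 3, 5], [1, 1, 0]
        t2, e2 = [2, 4, 6], [1, 1, 1]
        res = logrank_test([(t1, e1), (t2, e2)])
        assert res.statistic == pytest.approx(
            logrank_oracle_2group(t1, e1, t2, e2), abs=1e-10)
        assert res.df == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_instances_vs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6, size=2)
        t1 = rng.integers(1, 10, n1).tolist()
        t2 = rng.integers(1, 10, n2).tolist()
        e1 = rng.integers(0, 2, n1).tolist()
        e2 = rng.integers(0, 2, n2).tolist()
        if sum(e1) + sum(e2) == 0:
            e1[0] = 1
        res = logrank_test([(t1, e1), (t2, e2)])
        assert res.statistic == pytest.approx(
            logrank_oracle_2group(t1, e1, t2, e2), abs=1e-10)

    def test_matches_lifelines_k_groups(self):
        rng = np.random.default_rng(4)
        t = np.concatenate([rng.exponential(m, 40).round() + 1
                            for m in (5, 10, 20)])
        e = (rng.random(120) < 0.8).astype(int)
        g = np.repeat([0, 1, 2], 40)
        res = logrank_test([
            (t[g == i], e[g == i]) for i in range(3)
        ])
        ll = multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.df == 2

    def test_two_group_equals_squared_standardized_oe(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(8, 50).round() + 1
        e = (rng.random(50) < 0.7).astype(int)
        g = rng.integers(0, 2, 50)
        if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
            e[:] = 1
        res = logrank_test([(t[g == 0], e[g == 0]), (t[g == 1], e[g == 1])])
        # internal consistency: chi2 = ((O-E)/sqrt(V))^2 via the oracle
        assert res.statistic == pytest.approx(
            logrank_oracle_2group(t[g == 0].tolist(), e[g == 0].tolist(),
                                  t[g == 1].tolist(), e[g == 1].tolist()),
            abs=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(SurvivalError):
            logrank_test([([1, 2], [1, 1]), ([], [])])

    def test_pairwise_shape(self):
        groups = [([1, 2, 3], [1, 1, 1]), ([4, 5, 6], [1, 1, 1]),
                  ([7, 8, 9], [1, 1, 1])]
        tab = logrank_pairwise(groups, labels=["a", "b", "c"])
        assert len(tab) == 3
        assert set(tab.columns) == {"group_a", "group_b", "statistic", "p_value"}


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def simulate_cox_data(n, beta, rng, censor_at=None):
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / np.exp(beta * x))
    e = np.ones(n, dtype=int)
    if censor_at is not None:
        e = (t <= censor_at).astype(int)
        t = np.minimum(t, censor_at)
    return t, e, x


class TestCoxFit:
    def test_hr_recovery_simulation(self):
        rng = np.random.default_rng(42)
        t, e, x = simulate_cox_data(1000, np.log(3.0), rng)
        fit = cox_fit(t, e, x[:, None])
        hr = fit.params["hr"].iloc[0]
        assert 2.5 <= hr <= 3.6
        lo, hi = fit.params["ci_low"].iloc[0], fit.params["ci_high"].iloc[0]
        assert lo < hr < hi

    def test_null_model_loglik_equals_zero_coef(self):
        rng = np.random.default_rng(3)
        t, e, x = simulate_cox_data(50, 0.8, rng)
        null_fit = cox_fit(t, e, pd.DataFrame(index=range(50)))
        fit = cox_fit(t, e, x[:, None])
        assert null_fit.loglik == pytest.approx(fit.loglik_null, abs=1e-9)
        assert fit.loglik >= fit.loglik_null

    def test_matches_statsmodels_breslow_with_ties(self):
        rng = np.random.default_rng(10)
        n = 150
        x = rng.normal(size=(n, 2))
        t = np.ceil(rng.exponential(5 / np.exp(x @ [0.5, -0.3])))  # many ties
        e = (rng.random(n) < 0.8).astype(int)
        fit = cox_fit(t, e, x)
        sm_fit = PHReg(t, x, status=e, ties="breslow").fit()
        assert fit.params["coef"].to_numpy() == pytest.approx(
            sm_fit.params, abs=1e-6)
        assert fit.params["se"].to_numpy() == pytest.approx(
            sm_fit.bse, rel=1e-4)

    def test_matches_lifelines_no_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(11)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(5 / np.exp(0.7 * x))  # continuous: no ties
        e = (rng.random(n) < 0.75).astype(int)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        fit = cox_fit(t, e, df[["x"]])
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        # lifelines' own convergence tolerance limits the agreement
        assert fit.params["coef"].iloc[0] == pytest.approx(
            cph.params_["x"], abs=1e-4)

    def test_wald_p_uniform_under_null(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(200):
            t, e, x = simulate_cox_data(80, 0.0, rng)
            fit = cox_fit(t, e, x[:, None])
            pvals.append(fit.params["p"].iloc[0])
        # KS against uniform; generous threshold for 200 replicates
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 <= frac <= 0.10

    def test_hr_monotone_in_planted_effect(self):
        rng = np.random.default_rng(12)
        hrs = []
        for beta in (0.0, 0.5, 1.0, 1.5):
            t, e, x = simulate_cox_data(600, beta, rng)
            hrs.append(cox_fit(t, e, x[:, None]).params["hr"].iloc[0])
        assert all(a < b for a, b in zip(hrs[:-1], hrs[1:]))

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        t, e, x = simulate_cox_data(100, 1.0, rng)
        a = cox_fit(t, e, x[:, None]).params
        b = cox_fit(t, e, x[:, None]).params
        pd.testing.assert_frame_equal(a, b)

    def test_no_events_errors(self):
        with pytest.raises(SurvivalError):
            cox_fit([1, 2], [0, 0], np.array([[1.0], [0.0]]))

    def test_separation_flagged(self):
        # covariate perfectly orders deaths before censoring
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        try:
            fit = cox_fit(t, e, x[:, None])
            assert fit.separation_flag
        except SurvivalError:
            pass  # non-convergence with a reported gradient is acceptable


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

class TestStepwise:
    def make_frame(self, n, rng, signal_beta=1.2):
        x_signal = rng.integers(0, 2, n)
        x_noise = rng.integers(0, 2, n)
        t = np.ceil(rng.exponential(10 / np.exp(signal_beta * x_signal)))
        return pd.DataFrame({
            "os_months": t,
            "event": 1,
            "signal": np.where(x_signal == 1, "hi", "lo"),
            "noise": np.where(x_noise == 1, "a", "b"),
        })

    def test_noise_covariate_mostly_excluded(self):
        rng = np.random.default_rng(13)
        kept_noise = 0
        for _ in range(25):
            df = self.make_frame(120, rng)
            fit = stepwise_cox(df, [
                Covariate("signal", "signal", ("lo", "hi")),
                Covariate("noise", "noise", ("a", "b")),
            ])
            assert "signal" in fit.selected
            kept_noise += "noise" in fit.selected
        assert kept_noise <= 3  # ~5% entry rate; bound leaves slack

    def test_zero_candidates_null_model(self):
        rng = np.random.default_rng(14)
        df = self.make_frame(50, rng)
        fit = stepwise_cox(df, [])
        assert fit.selected == []
        assert len(fit.params) == 0

    def test_no_candidate_passes_gate_warns(self, caplog):
        rng = np.random.default_rng(15)
        df = self.make_frame(60, rng, signal_beta=0.0)
        fit = stepwise_cox(df, [Covariate("noise", "noise", ("a", "b"))])
        assert fit.selected == []

    def test_selection_path_logged(self):
        rng = np.random.default_rng(16)
        df = self.make_frame(80, rng)
        fit = stepwise_cox(df, [Covariate("signal", "signal", ("lo", "hi"))])
        assert any("gate" in line for line in fit.selection_log)
        assert any("enter signal" in line for line in fit.selection_log)


class TestKmByGroup:
    def test_groups_summarized(self):
        df = pd.DataFrame({
            "os_months": [2, 4, 6, 8, 10, 12],
            "event": [1, 1, 1, 1, 1, 1],
            "grp": ["a", "a", "a", "b", "b", "b"],
        })
        tab = km_by_group(df, "grp")
        assert list(tab["group"]) == ["a", "b"]
        assert list(tab["median"]) == [4, 10]

    def test_empty_group_row(self):
        df = pd.DataFrame({"os_months": [5], "event": [1], "grp": ["a"]})
        tab = km_by_group(df, "grp", group_order=["a", "b"])
        assert tab.loc[tab["group"] == "b", "n"].iloc[0] == 0
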