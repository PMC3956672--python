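"""Survival wrappers against brute-force oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest

from igfsurv.survival import (
    cox_fit,
    four_year_rate,
    interaction_test,
    km_fit,
    logrank_test,
    multivariate_model,
)

from oracles import cox_brute_force, km_brute_force, logrank_brute_force


def _random_survival(rng, n, beta=0.0):
    x = rng.integers(0, 2, size=n).astype(float)
    t = rng.exponential(scale=50.0 * np.exp(-beta * x))
    c = rng.uniform(10, 120, size=n)
    time = np.round(np.minimum(t, c), 1) + 0.1  # rounding creates ties
    event = (t <= c).astype(int)
    return time, event, x


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        time = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        event = np.ones(5, dtype=int)
        curve = km_fit(time, event)
        # with all events observed, S(t_(k)) = 1 - k/n
        np.testing.assert_allclose(curve.survival, [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_single_event_closed_form(self):
        n = 7
        time = np.array([5.0] + [10.0] * (n - 1))
        event = np.array([1] + [0] * (n - 1))
        curve = km_fit(time, event)
        assert curve.survival[0] == pytest.approx((n - 1) / n)
        # Greenwood: S^2 * d / (n (n - d)) = ((n-1)/n)^2 * 1/(n(n-1))
        assert curve.greenwood_var[0] == pytest.approx(
            ((n - 1) / n) ** 2 / (n * (n - 1))
        )

    def test_matches_brute_force_with_censoring_and_ties(self):
        rng = np.random.default_rng(7)
        time, event, _ = _random_survival(rng, 80)
        curve = km_fit(time, event)
        ts, surv = km_brute_force(time, event)
        np.testing.assert_allclose(curve.times, ts)
        np.testing.assert_allclose(curve.survival, surv, atol=1e-12)

    def test_exponential_consistency_at_48_months(self):
        rng = np.random.default_rng(11)
        lam = 1 / 120.0
        t = rng.exponential(scale=1 / lam, size=20000)
        c = np.full_like(t, 160.0)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        rate = four_year_rate(time, event)
        assert rate == pytest.approx(np.exp(-lam * 48.0), abs=0.01)

    def test_rate_before_first_event_is_one(self):
        curve = km_fit([10.0, 20.0], [1, 1])
        assert curve.rate_at(5.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one subject"):
            km_fit([], [])


class TestLogrank:
    def test_hand_computed_six_patients(self):
        # groups A: events at 1, 3; B: event at 2, censored at 4; A censored 5, 6
        time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        event = np.array([1, 1, 0, 1, 0, 0])
        group = np.array(["A", "A", "A", "B", "B", "B"])
        res = logrank_test(time, event, group)
        chi2 = logrank_brute_force(time, event, group)
        assert res.statistic == pytest.approx(chi2, rel=1e-9)
        assert res.df == 1

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(13)
        time, event, x = _random_survival(rng, 120, beta=0.5)
        res = logrank_test(time, event, np.where(x > 0, "high", "low"))
        chi2 = logrank_brute_force(time, event, x)
        assert res.statistic == pytest.approx(chi2, rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(17)
        time, event, x = _random_survival(rng, 60, beta=0.8)
        a = logrank_test(time, event, x)
        b = logrank_test(time, event, 1 - x)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_three_groups_two_df(self):
        rng = np.random.default_rng(19)
        time = rng.exponential(50, size=90)
        event = np.ones(90, dtype=int)
        group = np.repeat(["a", "b", "c"], 30)
        res = logrank_test(time, event, group)
        assert res.df == 2 and res.n_groups == 3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="at least one event"):
            logrank_test([1.0, 2.0], [0, 0], ["a", "b"])


class TestCox:
    def test_matches_brute_force_small_fixture(self):
        # 8 subjects, one tie, one censored observation
        time = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 8.0, 9.0, 12.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        fit = cox_fit(time, event, pd.DataFrame({"x": x}))
        beta = cox_brute_force(time, event, x[:, None])
        assert fit.summary.loc["x", "coef"] == pytest.approx(beta[0], abs=1e-6)

    def test_matches_brute_force_two_covariates(self):
        rng = np.random.default_rng(23)
        time, event, x = _random_survival(rng, 100, beta=0.7)
        z = rng.normal(size=100)
        X = pd.DataFrame({"x": x, "z": z})
        fit = cox_fit(time, event, X)
        beta = cox_brute_force(time, event, X.to_numpy())
        np.testing.assert_allclose(
            fit.summary["coef"].to_numpy(), beta, atol=1e-5
        )

    def test_hr_inverts_when_coding_flips(self):
        rng = np.random.default_rng(29)
        time, event, x = _random_survival(rng, 150, beta=0.6)
        f1 = cox_fit(time, event, pd.DataFrame({"x": x}))
        f2 = cox_fit(time, event, pd.DataFrame({"x": 1 - x}))
        assert f1.hr("x") == pytest.approx(1 / f2.hr("x"), rel=1e-6)

    def test_ci_is_wald_interval(self):
        rng = np.random.default_rng(31)
        time, event, x = _random_survival(rng, 120, beta=0.5)
        fit = cox_fit(time, event, pd.DataFrame({"x": x}))
        row = fit.summary.loc["x"]
        lo = np.exp(row["coef"] - 1.959963984540054 * row["se"])
        hi = np.exp(row["coef"] + 1.959963984540054 * row["se"])
        assert row["ci_lower"] == pytest.approx(lo, rel=1e-12)
        assert row["ci_upper"] == pytest.approx(hi, rel=1e-12)

    def test_efron_and_breslow_agree_without_ties(self):
        rng = np.random.default_rng(37)
        time = rng.exponential(50, size=80) + rng.uniform(0, 1e-3, size=80)
        x = rng.integers(0, 2, size=80).astype(float)
        event = np.ones(80, dtype=int)
        fe = cox_fit(time, event, pd.DataFrame({"x": x}), ties="efron")
        fb = cox_fit(time, event, pd.DataFrame({"x": x}), ties="breslow")
        assert fe.summary.loc["x", "coef"] == pytest.approx(
            fb.summary.loc["x", "coef"], abs=1e-4
        )

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="no contrast"):
            cox_fit([1.0, 2.0, 3.0], [1, 1, 1], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_more_covariates_than_events_refused(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.5], "b": [1.0, 0.0, 0.5]})
        with pytest.raises(ValueError, match="model refused"):
            cox_fit([1.0, 2.0, 3.0], [1, 0, 0], X)

    def test_unknown_ties_rejected(self):
        with pytest.raises(ValueError, match="unknown tie method"):
            cox_fit([1.0, 2.0], [1, 1], pd.DataFrame({"x": [0.0, 1.0]}), ties="exact")


class TestMultivariateModel:
    @staticmethod
    def _design(rng, n=400):
        x = rng.integers(0, 2, size=n).astype(float)       # real effect
        noise = rng.integers(0, 2, size=n).astype(float)   # no effect
        marker = rng.integers(0, 2, size=n).astype(float)  # combined variable
        t = rng.exponential(scale=60.0 * np.exp(-1.2 * x))
        c = rng.uniform(10, 150, size=n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        X = pd.DataFrame({"marker": marker, "x": x, "noise": noise})
        return time, event, X

    def test_alpha_one_keeps_full_model(self):
        rng = np.random.default_rng(41)
        time, event, X = self._design(rng)
        fit, kept = multivariate_model(time, event, X, "marker", alpha_stay=1.1)
        assert set(kept) == {"x", "noise"}
        assert set(fit.summary.index) == {"marker", "x", "noise"}

    def test_strong_effect_retained_noise_dropped(self):
        rng = np.random.default_rng(43)
        time, event, X = self._design(rng)
        fit, kept = multivariate_model(time, event, X, "marker", alpha_stay=0.15)
        assert "x" in kept and "noise" not in kept
        assert "marker" in fit.summary.index  # combined variable never eliminated

    def test_tiny_alpha_leaves_combined_alone(self):
        rng = np.random.default_rng(47)
        time, event, X = self._design(rng)
        fit, kept = multivariate_model(time, event, X, "marker", alpha_stay=1e-300)
        assert kept == []
        assert list(fit.summary.index) == ["marker"]

    def test_missing_combined_variable_rejected(self):
        rng = np.random.default_rng(53)
        time, event, X = self._design(rng)
        with pytest.raises(ValueError, match="not in design"):
            multivariate_model(time, event, X, "absent")


class TestInteraction:
    def test_constant_cluster_rejected(self):
        with pytest.raises(ValueError, match="no contrast"):
            interaction_test([1.0, 2.0, 3.0], [1, 1, 1], [1, 1, 1], [0, 1, 0])

    def test_null_interaction_p_in_unit_interval(self):
        rng = np.random.default_rng(59)
        n = 300
        cluster = rng.integers(0, 2, size=n)
        group = rng.integers(0, 2, size=n)
        t = rng.exponential(scale=60.0 * np.exp(-0.5 * cluster))
        c = rng.uniform(10, 150, size=n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        res = interaction_test(time, event, cluster, group)
        assert 0.0 < res["p_interaction"] <= 1.0
        assert res["fit"].converged
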