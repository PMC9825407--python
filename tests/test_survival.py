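"""Survival statistics: selection, median split, KM, log-rank, Cox with a
time-dependent covariate, Fisher exact and BH adjustment."""

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank

import cytoresponse as cr
from cytoresponse.core import ValidationError
from cytoresponse.survival import episode_split


class TestMedianSplit:
    def test_even_distinct_split_is_equal(self):
        rng = np.random.default_rng(0)
        groups = cr.median_split(rng.permutation(np.arange(32.0)))
        assert (groups == "low").sum() == 16
        assert (groups == "high").sum() == 16

    def test_odd_n_low_takes_median(self):
        groups = cr.median_split([1.0, 2.0, 3.0, 4.0, 5.0])
        assert (groups == "low").sum() == 3
        assert (groups == "high").sum() == 2

    def test_degenerate_split_errors(self):
        with pytest.raises(ValidationError, match="degenerate"):
            cr.median_split(np.ones(8))


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        out = cr.km_estimate([3.0, 5.0, 7.0], [0, 0, 0], ["g"] * 3)
        assert (out["g"]["survival"] == 1.0).all()

    def test_two_events_by_hand(self):
        out = cr.km_estimate([1.0, 2.0], [1, 1], ["g", "g"])["g"]
        s = dict(zip(out["time"], out["survival"]))
        assert s[1.0] == pytest.approx(0.5)
        assert s[2.0] == pytest.approx(0.0)

    def test_five_subject_product_limit_by_hand(self):
        # event 1, censored 2, event 3, censored 4, event 5
        out = cr.km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 1], ["g"] * 5)["g"]
        s = dict(zip(out["time"], out["survival"]))
        assert s[1.0] == pytest.approx(4 / 5)
        assert s[3.0] == pytest.approx(8 / 15)
        assert s[5.0] == pytest.approx(0.0)
        assert out["survival"].iloc[0] <= 1.0
        assert (np.diff(out["survival"]) <= 1e-12).all()

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError, match="empty"):
            cr.km_estimate([1.0], [1], np.array(["a"]), group_order=["a", "b"])


class TestLogRank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        ev = np.array([1, 0, 1, 1] * 2)
        g = np.array(["A"] * 4 + ["B"] * 4)
        res = cr.logrank_test(t, ev, g, group_order=("A", "B"))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_tabulated_expected_and_hr(self):
        # A events at 1,2; B events at 3,4 -> E_A = 1/2 + 1/3 = 0.8333,
        # HR(A/B) = (2/0.8333)/(2/3.1667) = 3.80
        res = cr.logrank_test(
            [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], ["A", "A", "B", "B"],
            group_order=("A", "B"),
        )
        assert res.expected["A"] == pytest.approx(0.8333, abs=1e-4)
        assert res.hazard_ratio == pytest.approx(3.80, abs=0.01)
        assert res.hr_ci[0] < res.hazard_ratio < res.hr_ci[1]

    def test_statistic_matches_lifelines(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 30).round(1)  # rounding forces ties
        ev = (rng.random(30) < 0.7).astype(int)
        g = np.array(["A"] * 15 + ["B"] * 15)
        res = cr.logrank_test(t, ev, g, group_order=("A", "B"))
        ref = ll_logrank(t[g == "A"], t[g == "B"], ev[g == "A"], ev[g == "B"])
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_asymptotic_p_tracks_exhaustive_permutation_at_n8(self):
        # at n=8 the chi-square approximation is coarse; the permutation
        # reference and the asymptotic p agree within ~0.12 on these cases
        rng = np.random.default_rng(5)
        for _ in range(4):
            t = rng.exponential(10, 8).round(2)
            ev = (rng.random(8) < 0.8).astype(int)
            if ev.sum() < 2:
                continue
            g = np.array(["A"] * 4 + ["B"] * 4)
            res = cr.logrank_test(t, ev, g, group_order=("A", "B"))
            stats = []
            for idx in combinations(range(8), 4):
                gg = np.array(["B"] * 8)
                gg[list(idx)] = "A"
                stats.append(cr.logrank_test(t, ev, gg, group_order=("A", "B")).chi2)
            p_perm = float(np.mean(np.array(stats) >= res.chi2 - 1e-12))
            assert abs(res.p - p_perm) <= 0.12

    def test_no_events_errors(self):
        with pytest.raises(ValidationError, match="events"):
            cr.logrank_test([1.0, 2.0], [0, 0], ["A", "B"])


class TestCoxTimeDependent:
    def _surv(self, n=40, tx_frac=0.0, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.normal(50, 8, n)
        risk = rng.normal(size=n)
        t = rng.exponential(1 / (0.01 * np.exp(0.05 * (age - 50) + 0.5 * risk)))
        ev = (rng.random(n) < 0.8).astype(int)
        tx = np.full(n, np.nan)
        n_tx = int(tx_frac * n)
        if n_tx:
            cand = np.argsort(-t)[:n_tx]
            tx[cand] = t[cand] * rng.uniform(0.2, 0.8, n_tx)
        surv = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "time": t, "event": ev,
             "transplant_day": tx}
        )
        cov = pd.DataFrame({"patient_id": surv["patient_id"], "age": age, "risk": risk})
        return surv, cov

    def test_without_transplants_matches_plain_cox(self):
        surv, cov = self._surv()
        summary, dropped = cr.fit_cox_td(surv, cov)
        df = cov.copy()
        df["time"] = surv["time"].to_numpy()
        df["event"] = surv["event"].to_numpy()
        cph = CoxPHFitter().fit(df.drop(columns="patient_id"), "time", "event")
        for c in ("age", "risk"):
            assert summary.loc[c, "log_hr"] == pytest.approx(cph.params_[c], abs=1e-6)
        assert "transplant" in dropped  # constant 0 -> inestimable, dropped

    def test_episode_splitting_conserves_follow_up(self):
        surv, _ = self._surv(tx_frac=0.3, seed=1)
        long = episode_split(surv)
        follow = long.groupby("patient_id").apply(
            lambda g: (g["stop"] - g["start"]).sum(), include_groups=False
        )
        expected = surv.set_index("patient_id")["time"]
        pd.testing.assert_series_equal(
            follow.sort_index(), expected.sort_index(), check_names=False
        )
        # events land only on the final episode
        assert long.groupby("patient_id")["event"].sum().max() <= 1

    def test_transplant_after_observed_time_rejected(self):
        surv, _ = self._surv()
        surv.loc[0, "transplant_day"] = surv.loc[0, "time"] + 1
        with pytest.raises(ValidationError, match="before"):
            episode_split(surv)

    def test_td_fit_runs_with_transplants(self):
        surv, cov = self._surv(tx_frac=0.3, seed=2)
        summary, dropped = cr.fit_cox_td(surv, cov)
        assert "transplant" in summary.index
        assert np.isfinite(summary["log_hr"]).all()


class TestFisherExact:
    def test_unit_diagonal(self):
        assert cr.fisher_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_zero_margin(self):
        assert cr.fisher_exact([[0, 0], [3, 5]]) == 1.0

    def test_hand_enumerated_value(self):
        assert cr.fisher_exact([[6, 10], [3, 13]]) == pytest.approx(0.4331, abs=1e-4)

    def test_matches_scipy_and_exact_enumeration(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(2)
        for _ in range(30):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            ours = cr.fisher_exact(t)
            a, b, c, d = t.ravel()
            n, r1, c1 = t.sum(), a + b, a + c
            denom = comb(n, r1)
            pmf = {
                k: comb(c1, k) * comb(n - c1, r1 - k) / denom
                for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            }
            exact = sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-7))
            assert ours == pytest.approx(min(exact, 1.0), abs=1e-10)
            assert ours == pytest.approx(scipy_fisher(t)[1], abs=1e-7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            cr.fisher_exact([[1, -2], [0, 3]])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert cr.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(cr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert (cr.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            cr.bh_adjust([0.5, 1.2])


class TestApplyHorizon:
    def test_caps_time_and_event(self):
        t, ev = cr.apply_horizon([100.0, 800.0, 2000.0], [1, 1, 1], "2y")
        assert t.tolist() == [100.0, 730.0, 730.0]
        assert ev.tolist() == [1, 0, 0]

    def test_five_year_horizon(self):
        t, ev = cr.apply_horizon([1825.0, 1827.0], [1, 1], "5y")
        assert ev.tolist() == [1, 0]


class TestNestedLOOCV:
    def _problem(self, seed, n=30, p=12, beta=2.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        z = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std()
        t = rng.exponential(1 / (0.01 * np.exp(beta * z)))
        return pd.DataFrame(X), np.minimum(t, 400), (t <= 400).astype(int)

    def test_deterministic(self):
        X, t, ev = self._problem(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cr.nested_loocv_select(X, t, ev, n_lambdas=8)
            b = cr.nested_loocv_select(X, t, ev, n_lambdas=8)
        assert a.selected_features == b.selected_features
        pd.testing.assert_series_equal(a.selection_frequency, b.selection_frequency)
        assert a.chosen_lambda == b.chosen_lambda

    def test_causal_feature_selected_with_strong_signal(self):
        hits = 0
        for seed in range(5):
            X, t, ev = self._problem(seed)
            res = cr.nested_loocv_select(X, t, ev, n_lambdas=8)
            hits += res.selection_frequency.index[0] == 0
        assert hits >= 4

    def test_null_model_mostly_empty(self):
        empties = 0
        for seed in range(6):
            X, t, ev = self._problem(100 + seed, beta=0.0)
            res = cr.nested_loocv_select(X, t, ev, n_lambdas=8)
            empties += len(res.selected_features) == 0
        assert empties >= 4

    def test_refit_table_reports_per_sd_loghr_and_adjusted_p(self):
        X, t, ev = self._problem(1)
        res = cr.nested_loocv_select(X, t, ev, n_lambdas=8)
        if res.selected_features:
            assert {"log_hr", "se", "p", "p_adj"} <= set(res.refit.columns)
            assert (res.refit["p_adj"] >= res.refit["p"] - 1e-12).all()
            assert set(res.univariate_p.index) == set(res.selected_features)

    def test_too_few_patients_rejected(self):
        X, t, ev = self._problem(0, n=8)
        with pytest.raises(ValidationError, match="n >= 10"):
            cr.nested_loocv_select(X, t, ev)
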