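"""Standardization, VIF, logistic IRLS, and binned-rate model tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import treemort as tm
from treemort.driver_models import (
    DEFAULT_INCREMENTS,
    binned_rates,
    fit_rate_model,
)
from treemort.scenario import HazardModel
from treemort.synthetic_forest import sample_tree_table


class TestPrepareCovariates:
    def _records(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "height": rng.lognormal(2.8, 0.4, n).clip(5, 60),
            "vpd_max": rng.uniform(1.2, 2.6, n),
            "slope_pct": rng.uniform(0, 40, n),
        })

    def test_constant_column_rejected_by_name(self):
        rec = self._records()
        rec["vpd_max"] = 1.5
        with pytest.raises(ValueError, match="vpd_max"):
            tm.prepare_covariates(rec)

    def test_standardized_moments(self):
        m = tm.prepare_covariates(self._records())
        assert np.allclose(m.X.mean(), 0.0, atol=1e-8)
        assert np.allclose(m.X.std(ddof=0), 1.0, atol=1e-8)

    def test_round_trip_back_transform(self):
        rec = self._records()
        m = tm.prepare_covariates(rec)
        for col in ("height", "vpd_max", "slope_pct"):
            back = m.back_transform(col, m.X[col].to_numpy())
            np.testing.assert_allclose(back, rec[col].to_numpy(), rtol=1e-10)

    def test_percent_anomaly_conversion_against_normals(self):
        rec = self._records()
        rec["tmax"] = np.linspace(10, 14, len(rec))
        m = tm.prepare_covariates(rec, columns=["tmax", "vpd_max"],
                                  normals={"tmax": 12.0})
        anomaly = 100.0 * (rec["tmax"] - 12.0) / 12.0
        np.testing.assert_allclose(
            m.back_transform("tmax", m.X["tmax"].to_numpy()), anomaly, rtol=1e-10)


class TestVif:
    def test_orthogonal_columns_have_unit_vif(self):
        X = pd.DataFrame({"a": [1., -1., 1., -1.], "b": [1., 1., -1., -1.],
                          "c": [1., -1., -1., 1.]})
        X = pd.concat([X] * 3, ignore_index=True)
        vif = tm.compute_vif(X)
        np.testing.assert_allclose(vif["vif"], 1.0, atol=1e-10)
        assert not vif["flagged"].any()

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=50)})
        vif = tm.compute_vif(X)
        assert np.isinf(vif.loc["a", "vif"]) and vif.loc["a", "flagged"]

    def test_three_column_case_matches_auxiliary_regressions(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=80)})
        X["b"] = 0.6 * X["a"] + rng.normal(size=80)
        X["c"] = rng.normal(size=80)
        vif = tm.compute_vif(X)
        for col in X.columns:
            others = sm.add_constant(X.drop(columns=[col]).to_numpy())
            r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
            assert vif.loc[col, "vif"] == pytest.approx(1.0 / (1.0 - r2))


class TestFitLogistic:
    def test_intercept_only_equals_logit_of_proportion(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = pd.DataFrame(index=range(100))
        fit = tm.fit_logistic(X, y)
        assert fit.params["intercept"] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_two_by_two_table_reproduces_ad_bc_odds_ratio(self):
        # tall: 20/100 dead; short: 10/100 -> OR = (20*90)/(80*10) = 2.25
        tall = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
        fit = tm.fit_logistic(pd.DataFrame({"tall": tall}), y)
        assert np.exp(fit.params["tall"]) == pytest.approx(2.25, abs=1e-6)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            tm.fit_logistic(pd.DataFrame({"x": [1., 2., 3.]}), np.zeros(3))

    def test_loglik_monotone_and_gradient_vanishes(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=500)})
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * X["x"])))
        y = (rng.random(500) < p).astype(float)
        fit = tm.fit_logistic(X, y)
        assert fit.converged
        assert (np.diff(fit.loglik_path) >= -1e-9).all()
        assert fit.grad_norm < 1e-6

    def test_matches_statsmodels_logit(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=400), "b": rng.normal(size=400)})
        p = 1 / (1 + np.exp(-(-0.5 + 0.7 * X["a"] - 0.3 * X["b"])))
        y = (rng.random(400) < p).astype(float)
        fit = tm.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, rtol=1e-4)

    def test_matches_brute_force_likelihood_grid(self):
        """Two-parameter fit agrees with an exhaustive likelihood search over
        a fine (intercept, slope) grid to within the grid pitch."""
        rng = np.random.default_rng(5)
        n = 150
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.4 + 0.9 * x)))
        y = (rng.random(n) < p).astype(float)
        fit = tm.fit_logistic(pd.DataFrame({"x": x}), y)
        b0g = np.arange(-1.5, 0.5, 0.002)
        b1g = np.arange(0.0, 2.0, 0.002)
        eta = b0g[:, None, None] + b1g[None, :, None] * x[None, None, :]
        ll = np.where(y == 1, -np.log1p(np.exp(-eta)), -np.log1p(np.exp(eta))).sum(-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert fit.params["intercept"] == pytest.approx(b0g[i], abs=1e-3)
        assert fit.params["x"] == pytest.approx(b1g[j], abs=1e-3)

    def test_complete_separation_raises_naming_variable(self):
        x = np.r_[np.full(20, -2.0), np.full(20, 2.0)]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(RuntimeError, match="x"):
            tm.fit_logistic(pd.DataFrame({"x": x}), y)


class TestOddsRatioReport:
    def _fit_and_matrix(self, beta_per_m=0.0231, n=120_000, seed=6):
        hz = HazardModel(form="logistic-status", b0=np.log(0.15 / 0.85) - beta_per_m * 18,
                         b_height=beta_per_m)
        t = sample_tree_table(n, seed, hazard=hz, years=1.0)
        m = tm.prepare_covariates(t, columns=["height"], transforms={})
        return tm.fit_logistic(m.X, t["dead"].to_numpy(float)), m

    def test_zero_coefficient_gives_unit_or(self):
        fit, m = self._fit_and_matrix()
        fit.params["height"] = 0.0
        rep = tm.odds_ratio_report(fit, m, increments={"height": 10.0})
        assert rep.loc["height", "or_per_sd"] == 1.0
        assert rep.loc["height", "or_per_increment"] == 1.0

    def test_linear_scale_coefficient_exponentiates_to_headline_or(self):
        # 0.0231 per metre over 10 m -> e^0.231 = 1.26 to 2 dp
        fit, m = self._fit_and_matrix()
        sd = m.meta.loc["height", "sd"]
        fit.params["height"] = 0.0231 * sd  # standardized-scale coefficient
        rep = tm.odds_ratio_report(fit, m, increments={"height": 10.0})
        assert rep.loc["height", "or_per_increment"] == pytest.approx(
            np.exp(0.231), rel=1e-12)
        assert round(rep.loc["height", "or_per_increment"], 2) == 1.26

    def test_negative_coefficient_tagged_risk_decreasing(self):
        fit, m = self._fit_and_matrix()
        fit.params["height"] = -0.2
        rep = tm.odds_ratio_report(fit, m)
        assert rep.loc["height", "or_per_sd"] < 1.0
        assert rep.loc["height", "direction"] == "risk-decreasing"

    def test_zero_increment_rejected(self):
        fit, m = self._fit_and_matrix()
        with pytest.raises(ValueError):
            tm.odds_ratio_report(fit, m, increments={"height": 0.0})


class TestReducedVpdModel:
    def _confounded_table(self, n=150_000, seed=7, with_dt_effect=True):
        # temperature carries part of the drought signal (dT is a near-copy
        # of VPD); dropping it must route that effect through VPD
        b_env = {"vpd_max": 0.2}
        if with_dt_effect:
            b_env["dt_pct"] = 0.02
        hz = HazardModel(form="logistic-status",
                         b0=np.log(0.12 / 0.88) - 0.0231 * 18 - 0.2 * 1.9,
                         b_height=0.0231, b_env=b_env)
        return sample_tree_table(n, seed, hazard=hz, years=1.0)

    def test_reduced_vpd_coefficient_exceeds_full_model(self):
        t = self._confounded_table()
        cols = ["height", "vpd_max", "dt_pct", "dppt_pct"]
        m_full = tm.prepare_covariates(t, columns=cols, transforms={})
        full = tm.fit_logistic(m_full.X, t["dead"].to_numpy(float))
        red_fit, _, m_red = tm.fit_reduced_vpd(t, columns=cols, transforms={})
        b_full = full.params["vpd_max"] / m_full.meta.loc["vpd_max", "sd"]
        b_red = red_fit.params["vpd_max"] / m_red.meta.loc["vpd_max", "sd"]
        # collinearity with dT/dPPT splits the VPD effect in the full model
        assert b_red > b_full

    def test_dropping_and_restoring_columns_is_a_noop(self):
        t = self._confounded_table(n=20_000)
        cols = ["height", "vpd_max"]
        m = tm.prepare_covariates(t, columns=cols, transforms={})
        a = tm.fit_logistic(m.X, t["dead"].to_numpy(float))
        b = tm.fit_logistic(m.X.copy(), t["dead"].to_numpy(float))
        pd.testing.assert_series_equal(a.params, b.params)

    def test_reduced_model_vifs_below_two(self):
        t = self._confounded_table(n=50_000)
        _, _, m = tm.fit_reduced_vpd(t)
        vif = tm.compute_vif(m.X)
        assert (vif["vif"] < 2.0).all()


class TestBinnedRates:
    def test_rate_arithmetic_with_two_year_lag(self):
        rec = pd.DataFrame({"height": np.full(50, 12.0),
                            "dead": np.r_[np.ones(10), np.zeros(40)]})
        tab = binned_rates(rec, bin_widths={"height": 5.0}, n_min=25)
        assert len(tab) == 1
        assert tab.iloc[0]["rate_pct_yr"] == pytest.approx(10.0)  # (10/50)/2*100

    def test_fully_dead_bin_caps_at_fifty_percent_per_year(self):
        rec = pd.DataFrame({"height": np.full(30, 12.0), "dead": np.ones(30)})
        tab = binned_rates(rec, bin_widths={"height": 5.0})
        assert tab.iloc[0]["rate_pct_yr"] == pytest.approx(50.0)

    def test_no_deaths_gives_zero_rate(self):
        rec = pd.DataFrame({"height": np.full(30, 12.0), "dead": np.zeros(30)})
        tab = binned_rates(rec, bin_widths={"height": 5.0})
        assert tab.iloc[0]["rate_pct_yr"] == 0.0

    def test_small_bins_excluded_and_counted(self):
        rec = pd.DataFrame({"height": np.r_[np.full(30, 12.0), np.full(5, 22.0)],
                            "dead": np.zeros(35)})
        tab = binned_rates(rec, bin_widths={"height": 5.0}, n_min=25)
        assert len(tab) == 1
        assert tab.attrs["n_excluded_small"] == 1

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            binned_rates(pd.DataFrame({"height": [], "dead": []}))


class TestRateModel:
    def _exact_table(self):
        rng = np.random.default_rng(8)
        h = rng.uniform(7, 40, 40)
        v = rng.uniform(1.2, 2.6, 40)
        rate = 2.0 + 0.3 * h + 4.0 * v
        return pd.DataFrame({"height": h, "vpd_max": v, "rate_pct_yr": rate,
                             "n": np.full(40, 100)})

    def test_noiseless_linear_table_recovered_exactly(self):
        tab = self._exact_table()
        fit, rep, m = fit_rate_model(tab, predictors=["height", "vpd_max"],
                                     transforms={})
        b_h = fit.params["height"] / m.meta.loc["height", "sd"]
        b_v = fit.params["vpd_max"] / m.meta.loc["vpd_max", "sd"]
        assert b_h == pytest.approx(0.3, abs=1e-8)
        assert b_v == pytest.approx(4.0, abs=1e-8)
        # per-increment conversion: 10 m of height -> 3 % per yr
        assert rep.loc["height", "rate_change_per_increment"] == pytest.approx(3.0,
                                                                               abs=1e-8)

    def test_three_row_system_matches_hand_solved_normal_equations(self):
        tab = pd.DataFrame({"height": [10.0, 20.0, 30.0],
                            "rate_pct_yr": [1.0, 3.0, 4.0],
                            "n": [10.0, 20.0, 30.0]})
        fit, _, m = fit_rate_model(tab, predictors=["height"], transforms={})
        # hand-solved WLS on the standardized column
        x = m.X["height"].to_numpy()
        y = tab["rate_pct_yr"].to_numpy()
        w = tab["n"].to_numpy()
        A = np.column_stack([np.ones(3), x])
        beta = np.linalg.solve(A.T @ (A * w[:, None]), A.T @ (w * y))
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_zero_weight_row_does_not_change_fit(self):
        tab = self._exact_table()
        extra = tab.iloc[[0]].copy()
        extra["rate_pct_yr"] = 99.0
        extra["n"] = 0.0
        tab2 = pd.concat([tab, extra], ignore_index=True)
        f1, _, _ = fit_rate_model(tab, predictors=["height", "vpd_max"],
                                  transforms={})
        f2, _, _ = fit_rate_model(tab2, predictors=["height", "vpd_max"],
                                  transforms={})
        b1 = f1.params["height"] / np.std(tab["height"])
        b2 = f2.params["height"] / np.std(tab2["height"])
        assert b1 == pytest.approx(b2, rel=1e-6)

    def test_too_few_rows_rejected(self):
        tab = self._exact_table().iloc[:3]
        with pytest.raises(ValueError):
            fit_rate_model(tab, predictors=["height", "vpd_max"], transforms={})


def test_increment_defaults_cover_reported_drivers():
    assert set(DEFAULT_INCREMENTS) == {"height", "vpd_max", "dt_pct",
                                       "dppt_pct", "soil_awc", "cover_pct"}
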