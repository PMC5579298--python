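"""Quasi-Poisson fitting and the two-step city models."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import thermoburden as tb
from thermoburden.city_models import _time_spline
from thermoburden.reduction import reduce_overall_cumulative


def _toy_series(n=30, flu=None, allcause=None):
    dates = pd.date_range("2001-01-01", periods=n, freq="D")
    return tb.CitySeries(
        city_id="toy", country="X", dates=dates,
        deaths={"nonacc": np.full(n, 5.0)},
        tmean=np.full(n, 10.0), tmin=np.full(n, 5.0), tmax=np.full(n, 15.0),
        influenza_deaths=flu, all_cause_deaths=allcause,
    )


class TestCitySeries:
    def test_date_gap_rejected(self):
        dates = pd.DatetimeIndex(["2001-01-01", "2001-01-02", "2001-01-04"])
        with pytest.raises(ValueError, match="non-consecutive"):
            tb.CitySeries(city_id="x", country="", dates=dates,
                          deaths={"nonacc": np.zeros(3)},
                          tmean=np.zeros(3), tmin=np.zeros(3), tmax=np.zeros(3))

    def test_negative_deaths_rejected(self):
        dates = pd.date_range("2001-01-01", periods=3, freq="D")
        with pytest.raises(ValueError, match="negative"):
            tb.CitySeries(city_id="x", country="", dates=dates,
                          deaths={"nonacc": np.array([1.0, -1.0, 0.0])},
                          tmean=np.zeros(3), tmin=np.zeros(3), tmax=np.zeros(3))

    def test_tmax_below_tmin_rejected(self):
        dates = pd.date_range("2001-01-01", periods=2, freq="D")
        with pytest.raises(ValueError, match="tmax"):
            tb.CitySeries(city_id="x", country="", dates=dates,
                          deaths={"nonacc": np.zeros(2)},
                          tmean=np.zeros(2), tmin=np.array([1.0, 1.0]),
                          tmax=np.array([2.0, 0.0]))


class TestInfluenzaIndicator:
    def test_zero_influenza(self):
        s = _toy_series(flu=np.zeros(30), allcause=np.full(30, 1000.0))
        assert tb.influenza_indicator(s).sum() == 0

    def test_threshold_ratio_one_per_thousand(self):
        s = _toy_series(flu=np.ones(30), allcause=np.full(30, 1000.0))
        ind = tb.influenza_indicator(s)
        np.testing.assert_array_equal(ind[:7], 0)
        np.testing.assert_array_equal(ind[7:], 1)

    def test_single_spike_flags_following_week(self):
        flu = np.zeros(30)
        flu[10] = 7.0
        s = _toy_series(flu=flu, allcause=np.full(30, 1000.0))
        ind = tb.influenza_indicator(s)
        assert list(np.where(ind == 1)[0]) == list(range(11, 18))


class TestQuasiPoisson:
    def test_intercept_only_closed_form(self):
        y = np.array([2.0, 4.0, 9.0, 5.0])
        coef, _, _, _ = tb.fit_quasipoisson(np.ones((4, 1)), y)
        assert coef[0] == pytest.approx(np.log(y.mean()), abs=1e-10)

    def test_simulation_recovery_within_3se(self):
        rng = np.random.default_rng(11)
        n = 5000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.5, 0.3])
        y = rng.poisson(np.exp(X @ beta))
        coef, vcov, _, _ = tb.fit_quasipoisson(X, y)
        se = np.sqrt(np.diag(vcov))
        assert np.all(np.abs(coef - beta) < 3 * se)

    def test_equidispersed_dispersion_near_one(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(10.0, size=20000)
        _, _, disp, _ = tb.fit_quasipoisson(np.ones((y.size, 1)), y)
        assert disp == pytest.approx(1.0, abs=0.1)

    def test_point_estimates_match_plain_poisson(self):
        rng = np.random.default_rng(3)
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        mu = np.exp(1.0 + 0.2 * X[:, 1])
        y = rng.negative_binomial(5, 5 / (5 + mu))  # overdispersed
        coef_qp, vcov_qp, disp, _ = tb.fit_quasipoisson(X, y)
        res_p = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(coef_qp, res_p.params, atol=1e-8)
        # vcov is the Poisson information inverse scaled by the dispersion
        np.testing.assert_allclose(vcov_qp, disp * res_p.cov_params(), rtol=1e-4)
        assert disp > 1.2  # clearly overdispersed

    def test_rank_deficiency_error(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="collinear"):
            tb.fit_quasipoisson(X, np.ones(10))


class TestTemperatureModel:
    def test_time_spline_df_one_year(self, small_city):
        _, series = small_city
        one_year = tb.CitySeries(
            city_id="y1", country="X", dates=series.dates[:366],
            deaths={"nonacc": series.deaths["nonacc"][:366]},
            tmean=series.tmean[:366], tmin=series.tmin[:366], tmax=series.tmax[:366],
        )
        B, _ = _time_spline(one_year, 8.0)
        assert B.shape[1] == 8

    def test_fit_contract(self, fitted_city):
        _, series, tfit, _ = fitted_city
        assert tfit.coef.shape == (25,)
        assert tfit.vcov.shape == (25, 25)
        np.testing.assert_allclose(tfit.vcov, tfit.vcov.T, atol=1e-10)
        assert tfit.dispersion > 0
        # first 28 days lost to lag embedding
        assert np.isnan(tfit.fitted_log_mu[:28]).all()
        assert tfit.n_days_used == series.n_days - 28

    def test_requires_a_year_of_data(self):
        cfg = tb.SimConfig(n_cities=1, years=1, rng_seed=1)
        s = tb.simulate_city(cfg, 0)
        short = tb.CitySeries(
            city_id="s", country="X", dates=s.dates[:120],
            deaths={"nonacc": s.deaths["nonacc"][:120]},
            tmean=s.tmean[:120], tmin=s.tmin[:120], tmax=s.tmax[:120],
        )
        with pytest.raises(ValueError, match="year"):
            tb.fit_temperature_model(short)

    def test_null_effect_wald_nonsignificant(self):
        """With no true temperature effect the cross-basis block should be
        non-significant at the 5% level in at least 90% of replicates."""
        from scipy import stats

        n_rep, hits = 40, 0
        for rep in range(n_rep):
            cfg = tb.SimConfig(
                n_cities=1, years=2, rng_seed=90000 + rep, overdispersion=1.0,
                truth=replace(tb.TruthConfig(), cold_slope=0.0, hot_slope=0.0,
                              dtr_cum_logrr_per_c=0.0),
            )
            s = tb.simulate_city(cfg, 0)
            fit = tb.fit_temperature_model(s)
            w = fit.coef @ np.linalg.solve(fit.vcov, fit.coef)
            p = stats.chi2.sf(w, fit.coef.size)
            hits += p > 0.05
        assert hits / n_rep >= 0.9

    def test_u_shaped_truth_recovered(self, fitted_city):
        """The reduced cumulative curve tracks the piecewise-linear truth;
        pointwise coverage is limited only near the spline-smoothed hinge."""
        cfg, series, tfit, _ = fitted_city
        from thermoburden.reduction import predict_rr
        from thermoburden.synthetic import _v_curve, true_mmt

        grid = np.percentile(series.tmean, np.linspace(1, 99, 99))
        tm = true_mmt(cfg, series.tmean)
        truth = _v_curve(grid, tm, cfg.truth.cold_slope, cfg.truth.hot_slope)
        curve = reduce_overall_cumulative(tfit).centered_at(tm)
        rr, lo, hi = predict_rr(curve, grid)
        coverage = np.mean((np.log(lo) <= truth) & (truth <= np.log(hi)))
        rmse = np.sqrt(np.mean((np.log(rr) - truth) ** 2))
        assert coverage >= 0.7
        assert rmse < 0.1
        # curve shape: higher risk at both tails than at the true MMT
        rr_t, _, _ = predict_rr(curve, np.array([grid[0], tm, grid[-1]]))
        assert rr_t[0] > rr_t[1] and rr_t[2] > rr_t[1]


class TestDTRModel:
    def test_constant_dtr_is_collinear_with_intercept(self, fitted_city):
        _, series, tfit, _ = fitted_city
        flat = tb.CitySeries(
            city_id=series.city_id, country="X", dates=series.dates,
            deaths=dict(series.deaths), tmean=series.tmean,
            tmin=series.tmean - 2.0, tmax=series.tmean + 2.0,
        )
        spec = tb.CrossBasisSpec(
            var_spec=tb.SplineSpec(kind="linear", boundary=(0, 10)),
            lag_spec=tb.SplineSpec(kind="natural_cubic", internal_knots=(2.41, 5.81),
                                   boundary=(0, 14), intercept=True),
            max_lag=14,
        )
        with pytest.raises(ValueError, match="collinear"):
            tb.fit_dtr_model(flat, tfit, dtr_spec=spec)

    def test_misaligned_fit_rejected(self, fitted_city):
        cfg, series, tfit, _ = fitted_city
        other = tb.simulate_city(tb.SimConfig(n_cities=1, years=1, rng_seed=9), 0)
        with pytest.raises(ValueError, match="align"):
            tb.fit_dtr_model(other, tfit)

    def test_null_dtr_estimates_center_on_zero(self):
        """Two-step orthogonality: zero DTR truth gives slope estimates
        centered on zero across replicates."""
        est = []
        for rep in range(30):
            cfg = tb.SimConfig(
                n_cities=1, years=3, rng_seed=70000 + rep,
                truth=replace(tb.TruthConfig(), dtr_cum_logrr_per_c=0.0),
            )
            s = tb.simulate_city(cfg, 0)
            f = tb.fit_temperature_model(s)
            d = tb.fit_dtr_model(s, f)
            est.append(reduce_overall_cumulative(d).coef[0])
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean()) < 2 * mc_se + 1e-4

    def test_known_dtr_slope_in_ci(self, fitted_city):
        cfg, series, tfit, dfit = fitted_city
        c = reduce_overall_cumulative(dfit)
        se = float(np.sqrt(c.vcov[0, 0]))
        truth = cfg.truth.dtr_cum_logrr_per_c
        assert c.coef[0] - 1.96 * se <= truth <= c.coef[0] + 1.96 * se


class TestInvariants:
    def test_vcov_scales_with_dispersion(self):
        rng = np.random.default_rng(21)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(1.0 + 0.1 * X[:, 1]))
        _, vcov, disp, _ = tb.fit_quasipoisson(X, y)
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        base = np.asarray(res.cov_params())
        np.testing.assert_allclose(vcov, disp * base, rtol=1e-4)
        np.testing.assert_allclose(2 * vcov, (2 * disp) * base, rtol=1e-4)
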