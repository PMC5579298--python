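"""Minimum-mortality temperature, attributable numbers/fractions, eCIs."""

import numpy as np
import pytest

import thermoburden as tb
from thermoburden.attribution import AttributionSpec, monte_carlo_eci
from thermoburden.reduction import ReducedCurve


def _linear_curve(slope, var=1e-4, boundary=(-50, 50)):
    return ReducedCurve(coef=np.array([slope]), vcov=np.array([[var]]),
                        var_spec=tb.SplineSpec(kind="linear", boundary=boundary))


def _quadratic_curve(center=20.0):
    """U-shaped curve with minimum at `center` on a quadratic spline basis."""
    spec = tb.SplineSpec(kind="bspline_quadratic", internal_knots=(15.0, 20.0, 25.0),
                         boundary=(0.0, 40.0))
    grid = np.linspace(0, 40, 200)
    B = tb.eval_basis(grid, spec)
    # constant offset chosen so the target vanishes at the left boundary,
    # where the intercept-free B-spline basis is pinned
    target = 0.002 * ((grid - center) ** 2 - center ** 2)
    coef, *_ = np.linalg.lstsq(B, target, rcond=None)
    return ReducedCurve(coef=coef, vcov=np.eye(spec.dim) * 1e-6, var_spec=spec)


class TestFindMMT:
    def test_symmetric_u_curve(self):
        rng = np.random.default_rng(0)
        temps = rng.uniform(0, 40, 4000)
        mmt, pct = tb.find_mmt(_quadratic_curve(20.0), temps)
        assert mmt == pytest.approx(20.0, abs=0.3)
        assert pct == pytest.approx(50.0, abs=3.0)

    def test_monotone_curve_hits_lower_search_bound(self):
        rng = np.random.default_rng(1)
        temps = rng.uniform(0, 40, 4000)
        mmt, _ = tb.find_mmt(_linear_curve(0.1, boundary=(0, 40)), temps)
        assert mmt == pytest.approx(np.percentile(temps, 1.0), abs=1e-9)

    def test_flat_curve_returns_median_with_warning(self):
        temps = np.linspace(0, 40, 1001)
        with pytest.warns(UserWarning, match="flat"):
            mmt, _ = tb.find_mmt(_linear_curve(0.0, boundary=(0, 40)), temps)
        assert mmt == pytest.approx(np.median(temps))


class TestAttributableNumbers:
    def test_hand_computed_example(self):
        """Three days, 10 deaths each, log-RR log(1.25): AN = 3*10*(1-0.8)=6."""
        curve = _linear_curve(np.log(1.25))
        an = tb.attributable_numbers(np.ones(3), np.full(3, 10.0), curve, center=0.0)
        assert an.sum() == pytest.approx(6.0, abs=1e-10)
        assert tb.attributable_fraction(an.sum(), 30) == pytest.approx(20.0)

    def test_null_curve_gives_zero(self):
        an = tb.attributable_numbers(np.ones(5), np.full(5, 7.0),
                                     _linear_curve(0.0), center=0.0)
        assert an.sum() == 0.0

    def test_empty_range_gives_zero(self):
        curve = _linear_curve(0.1)
        an = tb.attributable_numbers(np.ones(5), np.full(5, 7.0), curve,
                                     center=0.0, range_=(100.0, 200.0))
        assert an.sum() == 0.0

    def test_zero_deaths_total_rejected(self):
        with pytest.raises(ValueError):
            tb.attributable_fraction(1.0, 0)

    def test_brute_force_oracle(self, rng):
        """Total AN equals an independent day-by-day computation (1e-10)."""
        curve = _quadratic_curve(18.0)
        x = rng.uniform(0, 40, 300)
        deaths = rng.poisson(20, 300).astype(float)
        center = 18.0
        an = tb.attributable_numbers(x, deaths, curve, center=center)
        B = tb.eval_basis(x, curve.var_spec)
        Bc = tb.eval_basis(np.array([center]), curve.var_spec)
        brute = 0.0
        for t in range(300):
            b_t = float((B[t] - Bc[0]) @ curve.coef)
            brute += (1.0 - np.exp(-b_t)) * deaths[t]
        assert an.sum() == pytest.approx(brute, abs=1e-10)

    def test_partition_additivity(self, rng):
        """AFs over a disjoint partition of the exposure axis sum to the
        total AF (1e-8)."""
        curve = _quadratic_curve(22.0)
        x = rng.uniform(0, 40, 500)
        deaths = rng.poisson(15, 500).astype(float)
        total = tb.attributable_numbers(x, deaths, curve, center=22.0).sum()
        cuts = [(-np.inf, 10.0), (10.0, 25.0), (25.0, np.inf)]
        # half-open handling: make interior edges exclusive on the left
        parts = 0.0
        parts += tb.attributable_numbers(x, deaths, curve, 22.0, (-np.inf, 10.0)).sum()
        parts += tb.attributable_numbers(
            x, deaths, curve, 22.0, (np.nextafter(10.0, 11), 25.0)).sum()
        parts += tb.attributable_numbers(
            x, deaths, curve, 22.0, (np.nextafter(25.0, 26), np.inf)).sum()
        assert parts == pytest.approx(total, abs=1e-8)

    def test_block_splitting_invariance(self, rng):
        curve = _quadratic_curve(20.0)
        x = rng.uniform(0, 40, 400)
        deaths = rng.poisson(10, 400).astype(float)
        whole = tb.attributable_numbers(x, deaths, curve, 20.0).sum()
        split = sum(tb.attributable_numbers(x[i:i + 100], deaths[i:i + 100],
                                            curve, 20.0).sum()
                    for i in range(0, 400, 100))
        assert split == pytest.approx(whole, abs=1e-10)


class TestMonteCarloECI:
    def _setup(self, rng, var=1e-4):
        curve = _linear_curve(0.05, var=var)
        x = rng.uniform(0, 10, 200)
        deaths = rng.poisson(10, 200).astype(float)
        return curve, x, deaths

    def test_degenerate_vcov_collapses_to_point(self, rng):
        curve, x, deaths = self._setup(rng, var=0.0)
        spec = AttributionSpec(n_mc=200, rng_seed=1)
        lo, hi = monte_carlo_eci(curve, x, deaths, 0.0, None, spec)
        point = tb.attributable_fraction(
            tb.attributable_numbers(x, deaths, curve, 0.0).sum(), deaths.sum())
        assert lo == pytest.approx(point, abs=1e-10)
        assert hi == pytest.approx(point, abs=1e-10)

    def test_same_seed_reproducible(self, rng):
        curve, x, deaths = self._setup(rng)
        spec = AttributionSpec(n_mc=300, rng_seed=42)
        assert monte_carlo_eci(curve, x, deaths, 0.0, None, spec) == \
            monte_carlo_eci(curve, x, deaths, 0.0, None, spec)

    def test_wider_vcov_wider_interval(self, rng):
        curve, x, deaths = self._setup(rng, var=1e-4)
        curve2 = _linear_curve(0.05, var=4e-4)
        spec = AttributionSpec(n_mc=500, rng_seed=3)
        lo1, hi1 = monte_carlo_eci(curve, x, deaths, 0.0, None, spec)
        lo2, hi2 = monte_carlo_eci(curve2, x, deaths, 0.0, None, spec)
        assert hi2 - lo2 > hi1 - lo1

    def test_null_world_coverage(self):
        """When the true effect is zero, the 95% eCI should contain zero in
        roughly 95% of replicates (sampling coefficient around zero)."""
        rng = np.random.default_rng(77)
        x = rng.uniform(0, 10, 150)
        deaths = rng.poisson(12, 150).astype(float)
        spec = AttributionSpec(n_mc=400, rng_seed=5)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            est = rng.normal(0.0, 0.01)  # sampled estimate under zero truth
            curve = _linear_curve(est, var=1e-4)
            lo, hi = monte_carlo_eci(curve, x, deaths, 0.0, None, spec,
                                     rng=np.random.default_rng(rng.integers(2**31)))
            hits += lo <= 0.0 <= hi
        assert 0.90 <= hits / n_rep <= 0.99


class TestPerspectiveAndMmtOptions:
    def test_forward_equals_backward_for_constant_deaths(self, fitted_city):
        """With a flat death series the forward moving average equals the
        daily count away from the series edge, so both perspectives agree."""
        cfg, series, tfit, _ = fitted_city
        curve = tb.reduce_overall_cumulative(tfit)
        flat = tb.CitySeries(
            city_id=series.city_id, country="X", dates=series.dates,
            deaths={"nonacc": np.full(series.n_days, 20.0)},
            tmean=series.tmean, tmin=series.tmin, tmax=series.tmax,
        )
        kw = dict(cause="nonacc", start_day=28)
        back = tb.attribute_city(flat, curve, spec=AttributionSpec(n_mc=150, rng_seed=1), **kw)
        fwd = tb.attribute_city(flat, curve, spec=AttributionSpec(
            n_mc=150, rng_seed=1, perspective="forward"), **kw)
        # edge effect is at most the last 28 days' contribution
        assert fwd.af_total == pytest.approx(back.af_total, rel=0.05)

    def test_mmt_redraw_is_deterministic_and_runs(self, fitted_city):
        cfg, series, tfit, _ = fitted_city
        curve = tb.reduce_overall_cumulative(tfit)
        spec = AttributionSpec(n_mc=100, rng_seed=9, mmt_reestimate_per_draw=True)
        sl = slice(28, None)
        a = monte_carlo_eci(curve, series.tmean[sl], series.deaths["nonacc"][sl],
                            20.0, None, spec)
        b = monte_carlo_eci(curve, series.tmean[sl], series.deaths["nonacc"][sl],
                            20.0, None, spec)
        assert a == b
        assert a[0] < a[1]


class TestAttributionSpec:
    def test_percentile_ordering_enforced(self):
        with pytest.raises(ValueError):
            AttributionSpec(cold_upper_percentile=97.5, hot_lower_percentile=2.5)

    def test_an_af_consistency(self, fitted_city):
        """AN and AF agree through the deaths total on a real fit."""
        cfg, series, tfit, dfit = fitted_city
        curve = tb.reduce_overall_cumulative(tfit)
        spec = AttributionSpec(n_mc=150, rng_seed=0)
        res = tb.attribute_city(series, curve, cause="nonacc", spec=spec, start_day=28)
        assert res.an_total == pytest.approx(res.af_total / 100 * res.n_deaths, abs=1e-8)
        assert res.an_cold == pytest.approx(res.af_cold / 100 * res.n_deaths, abs=1e-8)
        assert res.an_hot == pytest.approx(res.af_hot / 100 * res.n_deaths, abs=1e-8)
        # MMT lies inside the search percentile band
        lo = np.percentile(series.tmean[28:], 1.0)
        hi = np.percentile(series.tmean[28:], 99.0)
        assert lo - 1e-9 <= res.mmt <= hi + 1e-9
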