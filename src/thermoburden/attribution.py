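"""Minimum-mortality temperature, attributable numbers/fractions, and
Monte Carlo empirical confidence intervals.

Attribution uses the backward perspective: the cumulative exposure-response
curve centered at the reference (the minimum-mortality temperature, or the
minimum observed DTR) gives the log relative risk ``b_t`` carried by day
``t``'s exposure; the deaths on that day attributable to the exposure are
``AN_t = (1 - exp(-b_t)) * deaths_t``.  Totals are sums over study days,
optionally restricted to an exposure range (e.g. below the 2.5th or above
the 97.5th temperature percentile for extreme cold/heat).  Uncertainty
comes from multivariate-normal Monte Carlo draws of the reduced (BLUP)
coefficients, with the reference held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .city_models import CitySeries
from .reduction import ReducedCurve, log_rr

__all__ = [
    "AttributionSpec",
    "AttributionResult",
    "find_mmt",
    "attributable_numbers",
    "attributable_fraction",
    "monte_carlo_eci",
    "attribute_city",
]


@dataclass(frozen=True)
class AttributionSpec:
    """Attribution settings.

    ``cold_upper_percentile`` / ``hot_lower_percentile`` bound the extreme
    ranges; the minimum-mortality temperature is searched between the
    ``mmt_search_percentile_range`` percentiles on a 0.1-percentile grid.
    """

    cold_upper_percentile: float = 2.5
    hot_lower_percentile: float = 97.5
    mmt_search_percentile_range: tuple[float, float] = (1.0, 99.0)
    n_mc: int = 5000
    rng_seed: int = 0
    dtr_reference: str = "min_observed"   # or "zero"
    perspective: str = "backward"         # or "forward"
    mmt_reestimate_per_draw: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.cold_upper_percentile < self.hot_lower_percentile < 100:
            raise ValueError("need 0 < cold_upper < hot_lower < 100")
        if self.n_mc < 100:
            raise ValueError("n_mc must be >= 100")
        if self.dtr_reference not in ("min_observed", "zero"):
            raise ValueError("dtr_reference must be 'min_observed' or 'zero'")
        if self.perspective not in ("backward", "forward"):
            raise ValueError("perspective must be 'backward' or 'forward'")


@dataclass
class AttributionResult:
    """Attributable fractions (percent) and numbers with 95% eCIs."""

    af_total: float
    af_total_ci: tuple[float, float]
    af_cold: float
    af_cold_ci: tuple[float, float]
    af_hot: float
    af_hot_ci: tuple[float, float]
    an_total: float
    an_cold: float
    an_hot: float
    mmt: float
    mmt_percentile: float
    n_deaths: float
    af_dtr: float | None = None
    af_dtr_ci: tuple[float, float] | None = None
    an_dtr: float | None = None


# ---------------------------------------------------------------------------
# Minimum mortality temperature
# ---------------------------------------------------------------------------

def find_mmt(
    curve: ReducedCurve,
    temps: np.ndarray,
    spec: AttributionSpec | None = None,
) -> tuple[float, float]:
    """Locate the minimum of the cumulative curve on the empirical
    percentile grid of the observed temperatures.

    Returns ``(mmt, mmt_percentile)``.  Ties, and a numerically flat
    curve, resolve toward the median temperature.
    """
    spec = spec or AttributionSpec()
    t = np.asarray(temps, dtype=float)
    t = t[~np.isnan(t)]
    if t.size == 0:
        raise ValueError("empty temperature series")
    lo, hi = spec.mmt_search_percentile_range
    pct_grid = np.arange(lo, hi + 1e-9, 0.1)
    grid = np.percentile(t, pct_grid)
    # uncentered curve values; argmin is invariant to the missing constant
    vals = log_rr(curve, grid, center=grid[0])
    med = np.median(t)
    if np.ptp(vals) < 1e-12:
        warnings.warn("flat exposure-response curve; MMT set to the median temperature")
        mmt = float(med)
    else:
        winners = np.where(vals <= vals.min() + 1e-12)[0]
        mmt = float(grid[winners[np.argmin(np.abs(grid[winners] - med))]])
    mmt_pct = float(np.mean(t <= mmt) * 100.0)
    return mmt, mmt_pct


# ---------------------------------------------------------------------------
# Attributable numbers and fractions
# ---------------------------------------------------------------------------

def _daily_an(
    exposure: np.ndarray,
    deaths: np.ndarray,
    coef: np.ndarray,
    curve: ReducedCurve,
    center: float,
    range_: tuple[float, float] | None,
) -> np.ndarray:
    """Daily attributable numbers for a given coefficient vector."""
    from .basis import eval_basis

    x = np.asarray(exposure, dtype=float)
    d = np.asarray(deaths, dtype=float)
    valid = ~np.isnan(x) & ~np.isnan(d)
    R = eval_basis(np.where(valid, x, center), curve.var_spec)
    Rc = eval_basis(np.array([center]), curve.var_spec)
    b = (R - Rc) @ coef
    an = (1.0 - np.exp(-b)) * d
    an[~valid] = 0.0
    if range_ is not None:
        lo, hi = range_
        inside = (x >= lo) & (x <= hi) & valid
        an = np.where(inside, an, 0.0)
    return an


def attributable_numbers(
    series_exposure: np.ndarray,
    deaths: np.ndarray,
    curve: ReducedCurve,
    center: float,
    range_: tuple[float, float] | None = None,
) -> np.ndarray:
    """Daily attributable-number series, backward perspective.

    Days with missing exposure or deaths contribute zero (their count is
    logged as a warning); days outside ``range_`` contribute zero.
    """
    x = np.asarray(series_exposure, dtype=float)
    d = np.asarray(deaths, dtype=float)
    n_missing = int(np.sum(np.isnan(x) | np.isnan(d)))
    if n_missing:
        warnings.warn(f"{n_missing} day(s) with missing data contribute 0 attributable deaths")
    return _daily_an(x, d, curve.coef, curve, center, range_)


def attributable_fraction(an_total: float, deaths_total: float) -> float:
    """Attributable fraction in percent: 100 * AN / total deaths."""
    if deaths_total <= 0:
        raise ValueError("deaths_total must be positive")
    return 100.0 * an_total / deaths_total


def monte_carlo_eci(
    curve: ReducedCurve,
    exposure: np.ndarray,
    deaths: np.ndarray,
    center: float,
    range_: tuple[float, float] | None,
    spec: AttributionSpec,
    rng: np.random.Generator | None = None,
    total_deaths: float | None = None,
) -> tuple[float, float]:
    """95% empirical CI of the attributable fraction from multivariate-normal
    draws of the curve coefficients.

    The reference is held at ``center`` unless
    ``spec.mmt_reestimate_per_draw`` is set, in which case each draw's
    curve is re-minimized over the observed-exposure percentile grid.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    # nearest-PSD repair of the coefficient covariance if needed
    V = (curve.vcov + curve.vcov.T) / 2
    evals, evecs = np.linalg.eigh(V)
    if evals.min() < -1e-8:
        warnings.warn("coefficient covariance repaired to nearest PSD")
    V = evecs @ np.diag(np.maximum(evals, 0.0)) @ evecs.T
    draws = rng.multivariate_normal(curve.coef, V, size=spec.n_mc, method="eigh")

    if spec.mmt_reestimate_per_draw:
        afs = np.empty(spec.n_mc)
        for m in range(spec.n_mc):
            draw_curve = ReducedCurve(coef=draws[m], vcov=curve.vcov,
                                      var_spec=curve.var_spec)
            c_m, _ = find_mmt(draw_curve, exposure, spec)
            afs[m] = _af_draws(curve, draws[m:m + 1], exposure, deaths, c_m,
                               range_, total_deaths)[0]
    else:
        afs = _af_draws(curve, draws, exposure, deaths, center, range_, total_deaths)
    return float(np.percentile(afs, 2.5)), float(np.percentile(afs, 97.5))


def _af_draws(
    curve: ReducedCurve,
    draws: np.ndarray,
    exposure: np.ndarray,
    deaths: np.ndarray,
    center: float,
    range_: tuple[float, float] | None,
    total_deaths: float | None = None,
) -> np.ndarray:
    """Attributable fraction per coefficient draw, vectorized over draws."""
    from .basis import eval_basis

    x = np.asarray(exposure, dtype=float)
    d = np.asarray(deaths, dtype=float)
    valid = ~np.isnan(x) & ~np.isnan(d)
    if range_ is not None:
        lo, hi = range_
        valid = valid & (x >= lo) & (x <= hi)
    if total_deaths is None:
        total_deaths = float(np.nansum(d))
    xv, dv = x[valid], d[valid]
    R = eval_basis(xv, curve.var_spec)
    Rc = eval_basis(np.array([center]), curve.var_spec)
    B = (R - Rc) @ draws.T                       # days x n_mc
    an = (1.0 - np.exp(-B)) * dv[:, None]
    return 100.0 * an.sum(axis=0) / total_deaths


# ---------------------------------------------------------------------------
# City-level attribution driver
# ---------------------------------------------------------------------------

def _forward_average(deaths: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean of deaths over days t..t+max_lag (forward perspective weight)."""
    d = np.asarray(deaths, dtype=float)
    n = d.size
    out = np.full(n, np.nan)
    for t in range(n):
        w = d[t:min(n, t + max_lag + 1)]
        out[t] = np.nanmean(w) if np.any(~np.isnan(w)) else np.nan
    return out


def attribute_city(
    series: CitySeries,
    temp_curve: ReducedCurve,
    dtr_curve: ReducedCurve | None = None,
    cause: str = "nonacc",
    spec: AttributionSpec | None = None,
    start_day: int = 0,
    rng: np.random.Generator | None = None,
    temp_lag: int = 28,
    dtr_lag: int = 14,
) -> AttributionResult:
    """Full attribution for one city: MMT, total/extreme-cold/extreme-hot
    temperature AFs and the DTR AF, each with Monte Carlo eCIs.

    ``start_day`` excludes the leading days lost to lag embedding so the
    attribution runs over the same days the models were fitted on.  Under
    ``spec.perspective == 'forward'`` the deaths attributable to day t's
    exposure are taken from the forward window t..t+L instead of day t
    itself; the AF denominator is the raw deaths total either way.
    """
    spec = spec or AttributionSpec()
    rng = rng or np.random.default_rng(spec.rng_seed)
    sl = slice(start_day, None)
    temps = series.tmean[sl]
    deaths = series.deaths[cause][sl]
    tv = temps[~np.isnan(temps)]

    mmt, mmt_pct = find_mmt(temp_curve, tv, spec)
    cold_hi = float(np.percentile(tv, spec.cold_upper_percentile))
    hot_lo = float(np.percentile(tv, spec.hot_lower_percentile))
    ranges = {
        "total": None,
        "cold": (-np.inf, cold_hi),
        "hot": (hot_lo, np.inf),
    }
    total_deaths = float(np.nansum(deaths))
    an_deaths = (_forward_average(deaths, temp_lag)
                 if spec.perspective == "forward" else deaths)
    an, ci = {}, {}
    for name, rg in ranges.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            daily = attributable_numbers(temps, an_deaths, temp_curve, mmt, rg)
        an[name] = float(daily.sum())
        ci[name] = monte_carlo_eci(temp_curve, temps, an_deaths, mmt, rg, spec,
                                   rng=rng, total_deaths=total_deaths)

    result = AttributionResult(
        af_total=attributable_fraction(an["total"], total_deaths),
        af_total_ci=ci["total"],
        af_cold=attributable_fraction(an["cold"], total_deaths),
        af_cold_ci=ci["cold"],
        af_hot=attributable_fraction(an["hot"], total_deaths),
        af_hot_ci=ci["hot"],
        an_total=an["total"],
        an_cold=an["cold"],
        an_hot=an["hot"],
        mmt=mmt,
        mmt_percentile=mmt_pct,
        n_deaths=total_deaths,
    )

    if dtr_curve is not None:
        dtr = series.dtr[sl]
        dv = dtr[~np.isnan(dtr)]
        ref = float(dv.min()) if spec.dtr_reference == "min_observed" else 0.0
        d_deaths = (_forward_average(deaths, dtr_lag)
                    if spec.perspective == "forward" else deaths)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            daily = attributable_numbers(dtr, d_deaths, dtr_curve, ref, None)
        result.an_dtr = float(daily.sum())
        result.af_dtr = attributable_fraction(result.an_dtr, total_deaths)
        result.af_dtr_ci = monte_carlo_eci(dtr_curve, dtr, d_deaths, ref, None,
                                           spec, rng=rng, total_deaths=total_deaths)
    return result
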