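"""First-step temperature model and second-step DTR model for one city.

The first step is a quasi-Poisson time-series regression of daily death
counts on a 28-day-lag temperature cross-basis, day-of-week indicators and
a natural cubic spline of calendar time with 8 degrees of freedom per year
(plus an optional influenza-epidemic indicator):

    log(mu_t) = b0 + crossbasis(TEMP)_t + DOW_t + ns(time_t)

The second step removes the fitted temperature/season/trend signal by
using log(mu_hat_t) from the first step as a fixed offset, and regresses
the counts on a 14-day-lag linear-exposure DTR cross-basis.  Two-step
fitting avoids the non-identifiability between correlated temperature
indices fitted jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import (
    CrossBasisSpec,
    SplineSpec,
    build_crossbasis,
    dtr_crossbasis_spec,
    eval_basis,
    temperature_crossbasis_spec,
)

__all__ = [
    "CitySeries",
    "FirstStageSpec",
    "CityFit",
    "DTRFit",
    "influenza_indicator",
    "fit_quasipoisson",
    "fit_temperature_model",
    "fit_dtr_model",
]


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class CitySeries:
    """One city's daily mortality and weather series.

    ``deaths`` maps cause name (e.g. ``nonacc``, ``cvd``, ``resp``) to a
    non-negative integer count series.  Dates must be strictly consecutive
    calendar days.  DTR is tmax - tmin.
    """

    city_id: str
    country: str
    dates: pd.DatetimeIndex
    deaths: dict[str, np.ndarray]
    tmean: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    influenza_deaths: np.ndarray | None = None
    all_cause_deaths: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.dates)
        self.dates = pd.DatetimeIndex(self.dates)
        if n >= 2:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("non-consecutive dates")
        for name in ("tmean", "tmin", "tmax"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"{name} length {arr.size} != {n} dates")
            setattr(self, name, arr)
        for cause, y in self.deaths.items():
            y = np.asarray(y)
            if y.size != n:
                raise ValueError(f"deaths[{cause}] length mismatch")
            ok = np.isnan(y.astype(float)) | (y.astype(float) >= 0)
            if not ok.all():
                raise ValueError(f"deaths[{cause}] contains negative counts")
            self.deaths[cause] = y.astype(float)
        both = ~np.isnan(self.tmin) & ~np.isnan(self.tmax)
        if np.any(self.tmax[both] < self.tmin[both]):
            raise ValueError("tmax < tmin")

    @property
    def dtr(self) -> np.ndarray:
        return self.tmax - self.tmin

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def n_years(self) -> float:
        return self.n_days / 365.25

    def day_of_week(self) -> np.ndarray:
        """0 = Monday ... 6 = Sunday."""
        return self.dates.dayofweek.to_numpy()


@dataclass(frozen=True)
class FirstStageSpec:
    """Configuration of the first-step model."""

    crossbasis: CrossBasisSpec | None = None  # None -> default from the data
    time_df_per_year: float = 8.0
    include_dow: bool = True
    include_influenza: bool = False

    def __post_init__(self) -> None:
        if self.time_df_per_year <= 0:
            raise ValueError("time_df_per_year must be > 0")


@dataclass
class CityFit:
    """Cross-basis coefficient block of a fitted first-step model."""

    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    fitted_log_mu: np.ndarray      # over all days; NaN where not fitted
    n_days_used: int
    spec: CrossBasisSpec
    city_id: str | None = None
    cause: str | None = None

    def __post_init__(self) -> None:
        if self.coef.size != self.spec.dim:
            raise ValueError("coefficient / cross-basis dimension mismatch")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
            raise ValueError("vcov not symmetric")

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "vcov": self.vcov.tolist(),
            "dispersion": self.dispersion,
            "n_days_used": self.n_days_used,
            "spec": self.spec.to_dict(),
            "city_id": self.city_id,
            "cause": self.cause,
        }


class DTRFit(CityFit):
    """Second-step fit over the DTR cross-basis columns (same contract)."""


# ---------------------------------------------------------------------------
# Influenza indicator
# ---------------------------------------------------------------------------

def influenza_indicator(series: CitySeries) -> np.ndarray:
    """Binary epidemic indicator: 1 on day t when the mean over the previous
    seven days of influenza deaths per 1000 all-cause deaths is >= 1.
    """
    if series.influenza_deaths is None or series.all_cause_deaths is None:
        raise ValueError("influenza_deaths and all_cause_deaths required")
    flu = np.asarray(series.influenza_deaths, dtype=float)
    ac = np.asarray(series.all_cause_deaths, dtype=float)
    ratio = np.zeros_like(flu)
    pos = ac > 0
    ratio[pos] = 1000.0 * flu[pos] / ac[pos]
    if np.any(~pos):
        warnings.warn(
            f"{int(np.sum(~pos))} day(s) with zero all-cause deaths treated as "
            "ratio 0 in the influenza indicator"
        )
    n = flu.size
    ind = np.zeros(n, dtype=int)
    csum = np.concatenate([[0.0], np.cumsum(ratio)])
    for t in range(7, n):
        window_mean = (csum[t] - csum[t - 7]) / 7.0
        ind[t] = 1 if window_mean >= 1.0 else 0
    return ind


# ---------------------------------------------------------------------------
# Quasi-Poisson fitting
# ---------------------------------------------------------------------------

def _check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a culprit set via QR pivoting on the correlation structure
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = np.where(diag < 1e-8 * diag.max())[0]
        labels = [names[i] if names else str(i) for i in bad]
        raise ValueError(f"rank-deficient design; collinear columns: {labels}")


def fit_quasipoisson(
    design: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    column_names: list[str] | None = None,
):
    """Quasi-Poisson GLM: Poisson IRLS point estimates, Pearson-X2 dispersion,
    covariance ``dispersion * (X'WX)^-1``.

    Returns ``(coef, vcov, dispersion, fitted_mu)``.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative counts")
    _check_full_rank(X, column_names)
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels domain warnings on exp overflow
        res = model.fit(scale="X2", maxiter=100, tol=1e-9)
    if not res.converged:
        # statsmodels checks absolute deviance change; accept on relative
        # change < 1e-9, the criterion appropriate for count totals of any size
        dev = res.fit_history.get("deviance", [])
        rel = abs(dev[-1] - dev[-2]) / max(abs(dev[-1]), 1.0) if len(dev) >= 2 else np.inf
        if rel > 1e-9:
            raise RuntimeError(
                f"IRLS failed to converge after {res.fit_history['iteration']} iterations; "
                f"deviance trace: {dev[-5:]}"
            )
    coef = np.asarray(res.params)
    vcov = np.asarray(res.cov_params())
    dispersion = float(res.scale)
    fitted = np.asarray(res.mu)
    return coef, vcov, dispersion, fitted


# ---------------------------------------------------------------------------
# Design construction helpers
# ---------------------------------------------------------------------------

def _dow_columns(series: CitySeries) -> tuple[np.ndarray, list[str]]:
    """Six indicator columns, Monday as reference."""
    dow = series.day_of_week()
    cols = np.column_stack([(dow == d).astype(float) for d in range(1, 7)])
    return cols, [f"dow_{d}" for d in range(1, 7)]


def _time_spline(series: CitySeries, df_per_year: float) -> tuple[np.ndarray, list[str]]:
    """Natural cubic spline of the day index with round(df_per_year * years)
    total df, knots at equally spaced quantiles of the day index."""
    n = series.n_days
    df = max(2, round(df_per_year * series.n_years))
    t = np.arange(n, dtype=float)
    # ns without intercept: df = n_internal + 1  ->  n_internal = df - 1
    n_internal = df - 1
    qs = np.linspace(0, 100, n_internal + 2)[1:-1]
    knots = tuple(np.percentile(t, qs))
    spec = SplineSpec(
        kind="natural_cubic", internal_knots=knots, boundary=(0.0, float(n - 1)),
        intercept=False,
    )
    B = eval_basis(t, spec)
    return B, [f"time_ns_{i}" for i in range(B.shape[1])]


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

def fit_temperature_model(
    series: CitySeries,
    spec: FirstStageSpec | None = None,
    cause: str = "nonacc",
) -> CityFit:
    """Fit the first-step temperature model for one city and cause.

    Days without full 28-day lag history (or with any missing input) are
    excluded.  The returned fit carries the coefficient subvector and
    covariance block of the temperature cross-basis only, plus the full
    fitted log-means needed as the second-step offset.
    """
    spec = spec or FirstStageSpec()
    if series.n_years < 1.0:
        raise ValueError("at least one year of data required")
    if cause not in series.deaths:
        raise ValueError(f"cause {cause!r} not present")

    cb_spec = spec.crossbasis or temperature_crossbasis_spec(series.tmean)
    cb = build_crossbasis(series.tmean, cb_spec, series_id=series.city_id)

    parts = [np.ones((series.n_days, 1)), cb.matrix]
    names = ["intercept"] + [f"cb_{i}" for i in range(cb_spec.dim)]
    if spec.include_dow:
        dow, dow_names = _dow_columns(series)
        parts.append(dow)
        names += dow_names
    tspl, t_names = _time_spline(series, spec.time_df_per_year)
    parts.append(tspl)
    names += t_names
    if spec.include_influenza:
        parts.append(influenza_indicator(series).reshape(-1, 1).astype(float))
        names.append("flu_epidemic")

    X = np.column_stack(parts)
    y = series.deaths[cause]
    complete = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    if complete.sum() <= X.shape[1]:
        raise ValueError("insufficient data")

    coef, vcov, disp, fitted = fit_quasipoisson(
        X[complete], y[complete], column_names=names
    )
    cb_idx = slice(1, 1 + cb_spec.dim)
    log_mu = np.full(series.n_days, np.nan)
    log_mu[complete] = np.log(fitted)
    return CityFit(
        coef=coef[cb_idx],
        vcov=vcov[cb_idx, cb_idx],
        dispersion=disp,
        fitted_log_mu=log_mu,
        n_days_used=int(complete.sum()),
        spec=cb_spec,
        city_id=series.city_id,
        cause=cause,
    )


def fit_dtr_model(
    series: CitySeries,
    temp_fit: CityFit,
    dtr_spec: CrossBasisSpec | None = None,
    cause: str | None = None,
    include_intercept: bool = True,
) -> DTRFit:
    """Fit the second-step DTR model with the first-step fitted log-means as
    a fixed offset.

    The model's own intercept (default on) absorbs the mean DTR
    contribution already implicit in the offset, so the DTR coefficients
    measure departures from the average diurnal range.
    """
    if temp_fit.fitted_log_mu.size != series.n_days:
        raise ValueError("temperature fit not aligned with series")
    cause = cause or temp_fit.cause or "nonacc"
    dtr_spec = dtr_spec or dtr_crossbasis_spec(series.dtr)
    if dtr_spec.var_spec.kind != "linear":
        raise ValueError("DTR exposure-response must be linear")

    cb = build_crossbasis(series.dtr, dtr_spec, series_id=series.city_id)
    offset = temp_fit.fitted_log_mu
    y = series.deaths[cause]

    if include_intercept:
        X = np.column_stack([np.ones((series.n_days, 1)), cb.matrix])
        names = ["intercept"] + [f"dtr_cb_{i}" for i in range(dtr_spec.dim)]
        cb_idx = slice(1, 1 + dtr_spec.dim)
    else:
        X = cb.matrix
        names = [f"dtr_cb_{i}" for i in range(dtr_spec.dim)]
        cb_idx = slice(0, dtr_spec.dim)

    complete = ~np.isnan(X).any(axis=1) & ~np.isnan(y) & ~np.isnan(offset)
    if complete.sum() <= X.shape[1]:
        raise ValueError("insufficient data")

    coef, vcov, disp, fitted = fit_quasipoisson(
        X[complete], y[complete], offset=offset[complete], column_names=names
    )
    log_mu = np.full(series.n_days, np.nan)
    log_mu[complete] = np.log(fitted)
    return DTRFit(
        coef=coef[cb_idx],
        vcov=vcov[cb_idx, cb_idx],
        dispersion=disp,
        fitted_log_mu=log_mu,
        n_days_used=int(complete.sum()),
        spec=dtr_spec,
        city_id=series.city_id,
        cause=cause,
    )
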