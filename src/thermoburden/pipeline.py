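"""End-to-end two-stage pipeline over a directory of city CSVs.

Per-city CSV dialect: columns ``date`` (ISO 8601), ``deaths_nonacc``,
``deaths_cvd``, ``deaths_resp`` (any subset), ``tmean``, ``tmin``,
``tmax``, optional ``flu_deaths`` and ``allcause_deaths``; missing values
as empty fields.  An optional cities metadata CSV supplies ``city_id``,
``country`` and the meta-predictors (computed from the data when absent).

The pipeline fits the first-step temperature model and second-step DTR
model in every city, reduces to overall cumulative curves, pools them in
two multivariate meta-regressions (temperature and DTR), derives BLUPs,
locates each city's minimum-mortality temperature, computes attributable
fractions with Monte Carlo empirical CIs, and aggregates attributable
numbers to country and overall totals.  Every run writes a manifest
recording the configuration, seeds and package versions, so results are
reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import AttributionResult, AttributionSpec, attribute_city, _af_draws
from .basis import CrossBasisSpec
from .city_models import CityFit, CitySeries, DTRFit, FirstStageSpec, fit_dtr_model, fit_temperature_model
from .meta import BlupSet, MetaFit, MetaInput, compute_blups, fit_mvmeta
from .reduction import ReducedCurve, reduce_overall_cumulative
from .synthetic import SimConfig, simulate_cities

logger = logging.getLogger("thermoburden")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_city_csv",
    "validate_city_csv",
    "write_city_csv",
    "run_pipeline",
]

CAUSE_COLUMNS = {"nonacc": "deaths_nonacc", "cvd": "deaths_cvd", "resp": "deaths_resp"}


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_city_csv(series: CitySeries, path: str | Path) -> None:
    cols: dict[str, object] = {"date": series.dates.strftime("%Y-%m-%d")}
    for cause, col in CAUSE_COLUMNS.items():
        if cause in series.deaths:
            y = series.deaths[cause]
            cols[col] = y if np.isnan(y).any() else y.astype(int)
    cols["tmean"] = series.tmean
    cols["tmin"] = series.tmin
    cols["tmax"] = series.tmax
    if series.influenza_deaths is not None:
        cols["flu_deaths"] = series.influenza_deaths
    if series.all_cause_deaths is not None:
        cols["allcause_deaths"] = series.all_cause_deaths
    pd.DataFrame(cols).to_csv(path, index=False)


def read_city_csv(path: str | Path, city_id: str | None = None,
                  country: str = "") -> CitySeries:
    """Read and validate one city CSV; raises ValueError with row-level
    detail on invariant violations."""
    path = Path(path)
    df = pd.read_csv(path, parse_dates=["date"])
    problems: list[str] = []
    dates = pd.DatetimeIndex(df["date"])
    if len(dates) >= 2:
        gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        for i in np.where(gaps != 1)[0][:5]:
            problems.append(f"non-consecutive dates at {dates[i].date()} -> {dates[i+1].date()}")
    deaths = {}
    for cause, col in CAUSE_COLUMNS.items():
        if col in df.columns:
            y = df[col].to_numpy(dtype=float)
            bad = np.where(y < 0)[0]
            for i in bad[:5]:
                problems.append(f"negative deaths ({col}) on {dates[i].date()}")
            deaths[cause] = y
    if not deaths:
        problems.append("no death-count column found")
    for c in ("tmean", "tmin", "tmax"):
        if c not in df.columns:
            problems.append(f"missing column {c}")
    if not problems:
        tmin = df["tmin"].to_numpy(dtype=float)
        tmax = df["tmax"].to_numpy(dtype=float)
        both = ~np.isnan(tmin) & ~np.isnan(tmax)
        for i in np.where(both & (tmax < tmin))[0][:5]:
            problems.append(f"tmax < tmin on {dates[i].date()}")
    if problems:
        raise ValueError(f"{path.name}: " + "; ".join(problems))
    return CitySeries(
        city_id=city_id or path.stem,
        country=country,
        dates=dates,
        deaths=deaths,
        tmean=df["tmean"].to_numpy(dtype=float),
        tmin=df["tmin"].to_numpy(dtype=float),
        tmax=df["tmax"].to_numpy(dtype=float),
        influenza_deaths=df["flu_deaths"].to_numpy(dtype=float) if "flu_deaths" in df else None,
        all_cause_deaths=df["allcause_deaths"].to_numpy(dtype=float) if "allcause_deaths" in df else None,
    )


validate_city_csv = read_city_csv


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    input_dir: str | None = None          # directory of per-city CSVs
    cities_csv: str | None = None         # metadata: city_id, country[, avg_temp, temp_range]
    cause: str = "nonacc"
    first_stage: FirstStageSpec = field(default_factory=FirstStageSpec)
    dtr_crossbasis: CrossBasisSpec | None = None
    dtr_intercept: bool = True
    attribution: AttributionSpec = field(default_factory=AttributionSpec)
    meta_method: str = "reml"
    output_dir: str | None = None
    log_level: str = "INFO"
    simulate: SimConfig | None = None     # if set, generate instead of reading

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "first_stage" in kwargs:
            kwargs["first_stage"] = FirstStageSpec(**kwargs["first_stage"])
        if "attribution" in kwargs:
            kwargs["attribution"] = AttributionSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs["attribution"].items()})
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            kwargs["simulate"] = SimConfig(**kwargs["simulate"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis-determining configuration (output location
        and log level excluded)."""
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        payload = enc(self)
        payload.pop("output_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CityResult:
    series: CitySeries
    temp_fit: CityFit
    dtr_fit: DTRFit
    temp_curve: ReducedCurve
    dtr_curve: ReducedCurve
    attribution: AttributionResult | None = None


@dataclass
class PipelineResult:
    cities: list[CityResult]
    temp_meta: MetaFit | None
    dtr_meta: MetaFit | None
    temp_blups: BlupSet | None
    dtr_blups: BlupSet | None
    af_table: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _load_cities(config: PipelineConfig) -> list[CitySeries]:
    if config.simulate is not None:
        return simulate_cities(config.simulate, causes=(config.cause,))
    if config.input_dir is None:
        raise ValueError("either input_dir or simulate must be set")
    meta = None
    if config.cities_csv:
        meta = pd.read_csv(config.cities_csv).set_index("city_id")
    out = []
    for path in sorted(Path(config.input_dir).glob("*.csv")):
        country = ""
        if meta is not None and path.stem in meta.index:
            country = str(meta.loc[path.stem, "country"])
        try:
            out.append(read_city_csv(path, country=country))
        except ValueError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
    if not out:
        raise ValueError("no valid city series found")
    return out


def _fit_city(series: CitySeries, config: PipelineConfig) -> CityResult | None:
    try:
        tfit = fit_temperature_model(series, config.first_stage, cause=config.cause)
        dfit = fit_dtr_model(series, tfit, config.dtr_crossbasis,
                             include_intercept=config.dtr_intercept)
    except (ValueError, RuntimeError) as exc:
        logger.warning("city %s failed to fit: %s", series.city_id, exc)
        return None
    return CityResult(
        series=series,
        temp_fit=tfit,
        dtr_fit=dfit,
        temp_curve=reduce_overall_cumulative(tfit),
        dtr_curve=reduce_overall_cumulative(dfit),
    )


def _meta_inputs(results: list[CityResult], which: str) -> MetaInput:
    curves = [getattr(r, which) for r in results]
    y = np.vstack([c.coef for c in curves])
    S = np.stack([c.vcov for c in curves])
    avg_temp = np.array([np.nanmean(r.series.tmean) for r in results])
    temp_range = np.array([np.nanmax(r.series.tmean) - np.nanmin(r.series.tmean)
                           for r in results])
    countries = [r.series.country or "?" for r in results]
    n_countries = len(set(countries))
    return MetaInput.from_predictors(
        y, S,
        avg_temp=avg_temp,
        temp_range=temp_range,
        country=countries if n_countries > 1 else None,
        city_ids=[r.series.city_id for r in results],
    )


def _aggregate_af(
    results: list[CityResult],
    cause: str,
    spec: AttributionSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Country and overall AFs: attributable numbers and deaths summed
    across cities, Monte Carlo draws summed consistently per draw."""
    rows = []
    groups: dict[str, list[CityResult]] = {}
    for r in results:
        groups.setdefault(r.series.country or "all", []).append(r)
    if len(groups) > 1:
        groups["TOTAL"] = list(results)

    for gname, members in groups.items():
        sums = {k: 0.0 for k in ("an_total", "an_cold", "an_hot", "an_dtr", "deaths")}
        draw_sums = {k: np.zeros(spec.n_mc) for k in ("total", "cold", "hot", "dtr")}
        for r in members:
            a = r.attribution
            start = r.temp_fit.spec.max_lag
            sl = slice(start, None)
            deaths = r.series.deaths[cause][sl]
            temps = r.series.tmean[sl]
            sums["an_total"] += a.an_total
            sums["an_cold"] += a.an_cold
            sums["an_hot"] += a.an_hot
            sums["an_dtr"] += a.an_dtr or 0.0
            sums["deaths"] += a.n_deaths
            tv = temps[~np.isnan(temps)]
            cold_hi = float(np.percentile(tv, spec.cold_upper_percentile))
            hot_lo = float(np.percentile(tv, spec.hot_lower_percentile))
            draws = rng.multivariate_normal(
                r.temp_curve.coef, _psd(r.temp_curve.vcov), size=spec.n_mc, method="eigh")
            for key, rg in (("total", None), ("cold", (-np.inf, cold_hi)),
                            ("hot", (hot_lo, np.inf))):
                afs = _af_draws(r.temp_curve, draws, temps, deaths, a.mmt, rg)
                draw_sums[key] += afs / 100.0 * a.n_deaths
            dtr = r.series.dtr[sl]
            ref = float(np.nanmin(dtr)) if spec.dtr_reference == "min_observed" else 0.0
            ddraws = rng.multivariate_normal(
                r.dtr_curve.coef, _psd(r.dtr_curve.vcov), size=spec.n_mc, method="eigh")
            afs = _af_draws(r.dtr_curve, ddraws, dtr, deaths, ref, None)
            draw_sums["dtr"] += afs / 100.0 * a.n_deaths

        row = {"country": gname, "cause": cause, "n_deaths": sums["deaths"]}
        for key, an_key in (("temperature", "an_total"), ("cold", "an_cold"),
                            ("hot", "an_hot"), ("dtr", "an_dtr")):
            af = 100.0 * sums[an_key] / sums["deaths"]
            dist = 100.0 * draw_sums[{"temperature": "total"}.get(key, key)] / sums["deaths"]
            row[f"af_{key}"] = af
            row[f"af_{key}_low"] = float(np.percentile(dist, 2.5))
            row[f"af_{key}_high"] = float(np.percentile(dist, 97.5))
        rows.append(row)
    return pd.DataFrame(rows)


def _psd(V: np.ndarray) -> np.ndarray:
    V = (V + V.T) / 2
    evals, evecs = np.linalg.eigh(V)
    return evecs @ np.diag(np.maximum(evals, 0.0)) @ evecs.T


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full two-stage analysis; see the module docstring."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    series_list = _load_cities(config)
    results = [r for r in (_fit_city(s, config) for s in series_list) if r is not None]
    if not results:
        raise RuntimeError("every city failed to fit")
    logger.info("fitted %d/%d cities", len(results), len(series_list))

    temp_meta = dtr_meta = None
    temp_blups = dtr_blups = None
    if len(results) >= 2:
        t_in = _meta_inputs(results, "temp_curve")
        d_in = _meta_inputs(results, "dtr_curve")
        if t_in.n > t_in.p:
            temp_meta = fit_mvmeta(t_in, method=config.meta_method)
            temp_blups = compute_blups(t_in, temp_meta)
            dtr_meta = fit_mvmeta(d_in, method=config.meta_method)
            dtr_blups = compute_blups(d_in, dtr_meta)
            logger.info("temperature meta: Q=%.1f df=%d I2=%.1f%%",
                        temp_meta.Q, temp_meta.df_Q, temp_meta.I2)
        else:
            logger.warning("too few cities for meta-regression; using city estimates")
    else:
        logger.warning("single-city mode: pooling skipped")

    # attribution with BLUP curves when available, otherwise city curves
    rng = np.random.default_rng(config.attribution.rng_seed)
    for i, r in enumerate(results):
        tcurve = r.temp_curve
        dcurve = r.dtr_curve
        if temp_blups is not None:
            tcurve = ReducedCurve(coef=temp_blups.blup[i], vcov=temp_blups.blup_vcov[i],
                                  var_spec=r.temp_curve.var_spec)
            dcurve = ReducedCurve(coef=dtr_blups.blup[i], vcov=dtr_blups.blup_vcov[i],
                                  var_spec=r.dtr_curve.var_spec)
        r.attribution = attribute_city(
            r.series, tcurve, dcurve, cause=config.cause,
            spec=config.attribution, start_day=r.temp_fit.spec.max_lag, rng=rng,
            temp_lag=r.temp_fit.spec.max_lag, dtr_lag=r.dtr_fit.spec.max_lag,
        )

    af_table = _aggregate_af(results, config.cause, config.attribution, rng)

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "cause": config.cause,
        "n_cities": len(results),
        "meta_method": config.meta_method,
        "rng_seed": config.attribution.rng_seed,
        "basis": results[0].temp_fit.spec.to_dict(),
        "dtr_basis": results[0].dtr_fit.spec.to_dict(),
    }

    result = PipelineResult(
        cities=results,
        temp_meta=temp_meta,
        dtr_meta=dtr_meta,
        temp_blups=temp_blups,
        dtr_blups=dtr_blups,
        af_table=af_table,
        manifest=manifest,
    )
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.af_table.to_csv(out / "af_table.csv", index=False, float_format="%.6f")
    fits = {
        r.series.city_id: {
            "temperature": r.temp_fit.to_dict(),
            "dtr": r.dtr_fit.to_dict(),
            "mmt": r.attribution.mmt if r.attribution else None,
            "mmt_percentile": r.attribution.mmt_percentile if r.attribution else None,
        }
        for r in result.cities
    }
    with open(out / "city_fits.json", "w") as fh:
        json.dump(fits, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
    # exposure-response grids for plotting
    rows = []
    for r in result.cities:
        if r.attribution is None:
            continue
        t = r.series.tmean[~np.isnan(r.series.tmean)]
        grid = np.percentile(t, np.linspace(1, 99, 99))
        from .reduction import predict_rr
        curve = r.temp_curve.centered_at(r.attribution.mmt)
        rr, lo, hi = predict_rr(curve, grid)
        for g, a, b, c in zip(grid, rr, lo, hi):
            rows.append({"city_id": r.series.city_id, "tmean": g,
                         "rr": a, "rr_low": b, "rr_high": c})
    pd.DataFrame(rows).to_csv(out / "rr_curves.csv", index=False, float_format="%.6f")
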