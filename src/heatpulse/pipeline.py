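"""End-to-end orchestration: exposure -> first stage -> pooling -> burden.

`run_full` executes the whole two-stage chain per heatwave type on either a
synthetic panel or per-city CSV inputs, writes tabular artifacts stamped with
a configuration hash and the master seed, and returns the in-memory results.
Sensitivity variants (threshold percentile, minimum duration, binary
exposure, covariate df, pollutant adjustment) are plain configuration fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr_mod
from . import dlnm, exposure, meta, synth

log = logging.getLogger("heatpulse")

SUMMER_MONTHS = (6, 7, 8)
_ALLOWED_PERCENTILES = (90.0, 92.5, 95.0, 97.5)
_ALLOWED_DURATIONS = (2, 3, 4)


@dataclass
class RunConfig:
    """Full-run configuration.

    Exactly one input mode: ``input_dir`` with per-city CSVs, or the
    synthetic generator parameters.  Variant fields outside the standard
    menus require ``allow_nonstandard=True``.
    """

    input_dir: str | None = None
    n_cities: int = 4
    years: int = 10
    seed: int = 1
    heterogeneity_sd: float = 0.0
    population_effect: float = 0.0
    night_warming_offset: float = 1.0
    baseline_daily_deaths: float = 50.0
    cum_logrr_per_degree: float = 0.05
    overdispersion: float = 1.2

    percentile: float = 90.0
    window: int = 15
    min_duration: int = 2
    binary_exposure: bool = False
    humidity_df: int = 3
    adjust_pm10: bool = False
    adjust_o3: bool = False
    pooling_level: str = "region"
    nsim: int = 1000
    out_dir: str | None = None
    allow_nonstandard: bool = False

    def __post_init__(self):
        if not self.allow_nonstandard:
            if self.percentile not in _ALLOWED_PERCENTILES:
                raise ValueError(
                    f"percentile {self.percentile} outside menu {_ALLOWED_PERCENTILES}")
            if self.min_duration not in _ALLOWED_DURATIONS:
                raise ValueError(
                    f"min_duration {self.min_duration} outside menu {_ALLOWED_DURATIONS}")
            if not 3 <= self.humidity_df <= 5:
                raise ValueError("humidity_df must be within 3..5")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def exposure_chain(hourly: pd.Series, percentile: float = 90.0,
                   window: int = 15, min_duration: int = 2,
                   part: exposure.DayPartition | None = None):
    """Hourly series -> (daily summaries + thresholds, heatwave calendar,
    per-type CEHWI)."""
    daily = exposure.daily_summaries(hourly)
    thr = exposure.calendar_thresholds(daily, percentile=percentile, window=window)
    cal = exposure.classify_heatwaves(daily, thr, min_duration=min_duration)
    cehwi = exposure.compute_cehwi(hourly, thr, cal, part)
    return (daily, thr), cal, cehwi


def summer_days(index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    return index[index.month.isin(SUMMER_MONTHS)]


def binary_exposure_series(cehwi: pd.Series) -> pd.Series:
    return (cehwi > 0).astype(float)


@dataclass
class CityStageOne:
    city_id: str
    hw_type: str
    fit: dlnm.FirstStageFit
    reduced: dlnm.ReducedFit
    exposure: pd.Series
    deaths_summer: pd.Series
    n_event_days: int


def fit_city_type(city, cehwi: pd.DataFrame, hw_type: str, cfg: RunConfig,
                  min_positive: int = 15) -> CityStageOne | None:
    """First-stage fit for one city and heatwave type; returns None when the
    city has too few event days of that type to place exposure knots."""
    series = cehwi[f"cehwi_{hw_type}"]
    days = summer_days(series.index)
    # positive days feeding any summer lag window
    window = series.index.isin(days) | series.index.isin(
        pd.DatetimeIndex(np.concatenate([(days - pd.Timedelta(days=l)).values
                                         for l in range(1, dlnm.MAX_LAG + 1)])))
    relevant = series[window]
    if cfg.binary_exposure:
        series = binary_exposure_series(series)
        var_spec = None
        if int((relevant > 0).sum()) < min_positive:
            return None
    else:
        if int((relevant > 0).sum()) < min_positive:
            return None
        var_spec = dlnm.var_spec_from_exposure(series.to_numpy())
    cb = dlnm.build_cross_basis(series, days, var_spec)
    cov = dlnm.covariate_matrix(days, humidity=city.humidity,
                                humidity_df=cfg.humidity_df)
    try:
        fit = dlnm.fit_first_stage(city.deaths, cb, cov)
    except ValueError as exc:
        if "rank deficient" in str(exc):
            log.warning("stage1 city=%s type=%s skipped: %s", city.city_id,
                        hw_type, exc)
            return None
        raise
    red = dlnm.reduce_to_overall(fit)
    return CityStageOne(city_id=city.city_id, hw_type=hw_type, fit=fit,
                        reduced=red, exposure=series,
                        deaths_summer=city.deaths.reindex(days),
                        n_event_days=int((series > 0).sum()))


def _pooled_var_spec(stage_ones, boundary_pct: float = 99.0) -> dlnm.SplineSpec | None:
    """Pooled-prediction spline spec: city-average knots with the boundary at
    the simple mean of the city-specific 99th CEHWI percentiles."""
    specs = [s.reduced.var_spec for s in stage_ones]
    if any(sp is None for sp in specs):
        return None
    k1 = float(np.mean([sp.internal_knots[0] for sp in specs]))
    k2 = float(np.mean([sp.internal_knots[1] for sp in specs]))
    hi = float(np.mean([
        np.quantile(s.exposure[s.exposure > 0], boundary_pct / 100.0)
        for s in stage_ones]))
    hi = max(hi, k2 * 1.01)
    return dlnm.SplineSpec(internal_knots=(k1, k2), boundary_knots=(0.0, hi))


def load_panel_csv(input_dir) -> synth.SyntheticPanel:
    """Read a panel previously written with :func:`synth.write_panel_csv`."""
    d = pathlib.Path(input_dir)
    attrs = pd.read_csv(d / "attributes.csv")
    cities = []
    for _, row in attrs.iterrows():
        cid = row["city_id"]
        hourly = pd.read_csv(d / f"{cid}_hourly.csv", index_col="timestamp",
                             parse_dates=True)["temp_c"]
        daily = pd.read_csv(d / f"{cid}_daily.csv", index_col="date",
                            parse_dates=True)
        cities.append(synth.CityData(
            city_id=cid, hourly=hourly, humidity=daily["rh"],
            deaths=daily["deaths"],
            attributes=row.drop("city_id").to_dict(), surface_scale=float("nan")))
    return synth.SyntheticPanel(cities=cities, heterogeneity_sd=float("nan"),
                                climate=None, mortality=None)


def default_panel(cfg: RunConfig) -> synth.SyntheticPanel:
    climate = synth.ClimateScenario(
        years=cfg.years, night_warming_offset=cfg.night_warming_offset)
    surface = {t: synth.linear_surface(cfg.cum_logrr_per_degree)
               for t in exposure.HW_TYPES}
    mortality = synth.MortalityScenario(
        baseline_daily_deaths=cfg.baseline_daily_deaths,
        true_surface=surface, overdispersion=cfg.overdispersion)
    return synth.make_panel(
        cfg.n_cities, climate, mortality,
        heterogeneity_sd=cfg.heterogeneity_sd, seed=cfg.seed,
        population_effect=cfg.population_effect,
        exposure_fn=lambda h: exposure_chain(
            h, percentile=cfg.percentile, window=cfg.window,
            min_duration=cfg.min_duration)[2])


def run_full(cfg: RunConfig, panel: synth.SyntheticPanel | None = None) -> dict:
    """Execute exposure -> dlnm -> meta -> attribution for every heatwave
    type, optionally writing artifacts under ``cfg.out_dir``."""
    t0 = time.time()
    chash = cfg.config_hash()
    if panel is None:
        panel = load_panel_csv(cfg.input_dir) if cfg.input_dir else default_panel(cfg)
    results = {"config_hash": chash, "seed": cfg.seed, "types": {}}
    # exposure stage per city (shared across types); reuse the generator's
    # cached exposure when the panel carries one
    city_cehwi = {}
    for city in panel:
        if getattr(city, "cehwi", None) is not None:
            cehwi = city.cehwi
        else:
            cehwi = exposure_chain(
                city.hourly, percentile=cfg.percentile, window=cfg.window,
                min_duration=cfg.min_duration)[2]
        city_cehwi[city.city_id] = cehwi
        log.info("exposure city=%s event_days=%d", city.city_id,
                 int((cehwi > 0).any(axis=1).sum()))

    for hw_type in exposure.HW_TYPES:
        stage_ones = []
        for city in panel:
            s1 = fit_city_type(city, city_cehwi[city.city_id], hw_type, cfg)
            if s1 is not None:
                stage_ones.append(s1)
            log.info("stage1 city=%s type=%s fitted=%s", city.city_id, hw_type,
                     s1 is not None)
        if len(stage_ones) < 2:
            results["types"][hw_type] = {"skipped": f"only {len(stage_ones)} "
                                         "cities with enough event days"}
            continue
        etas = np.stack([s.reduced.eta for s in stage_ones])
        Ss = np.stack([s.reduced.S for s in stage_ones])
        fit = meta.mvmeta_reml(etas, Ss)
        het = meta.heterogeneity(etas, Ss)
        pooled_spec = _pooled_var_spec(stage_ones)
        if pooled_spec is None:
            grid = np.array([0.0, 1.0])
        else:
            grid = np.linspace(0.0, pooled_spec.boundary_knots[1], 30)
        curve = meta.pooled_curve(fit, pooled_spec, grid)
        blups = meta.blup(fit)
        city_attr = []
        for i, s in enumerate(stage_ones):
            red = dlnm.ReducedFit(eta=blups.coefs[i], S=blups.covs[i],
                                  var_spec=s.reduced.var_spec)
            cfg_a = attr_mod.AttributionConfig(nsim=cfg.nsim, seed=cfg.seed + i)
            city_attr.append(attr_mod.attributable_fraction(
                s.deaths_summer, s.exposure, red, cfg_a))
        regional = attr_mod.pooled_attribution(city_attr, cfg.nsim, cfg.seed)
        results["types"][hw_type] = {
            "n_cities": len(stage_ones),
            "meta": fit, "heterogeneity": het, "curve": curve,
            "blups": blups, "city_attribution": city_attr,
            "regional_attribution": regional,
            "stage_ones": stage_ones, "pooled_spec": pooled_spec,
        }
        log.info("pooled type=%s k=%d I2=%.1f AF=%.3f%%", hw_type,
                 len(stage_ones), het.I2, regional["af_pct"])

    if cfg.out_dir:
        _write_artifacts(cfg, results)
    results["elapsed_s"] = time.time() - t0
    return results


def _write_artifacts(cfg: RunConfig, results: dict) -> None:
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": results["config_hash"], "seed": cfg.seed}
    (out / "run_meta.json").write_text(
        json.dumps({**stamp, "config": dataclasses.asdict(cfg)}, indent=2,
                   default=str))
    rows = []
    for t, r in results["types"].items():
        if "skipped" in r:
            continue
        r["curve"].assign(type=t, **stamp).to_csv(
            out / f"pooled_curve_{t}.csv", index=False)
        fits = []
        for s in r["stage_ones"]:
            row = {"city_id": s.city_id, "type": t,
                   "n_event_days": s.n_event_days,
                   "dispersion": s.fit.dispersion, **stamp}
            for j, e in enumerate(s.reduced.eta):
                row[f"eta{j+1}"] = e
            for j in range(len(s.reduced.eta)):
                for kk in range(j, len(s.reduced.eta)):
                    row[f"S{j+1}{kk+1}"] = s.reduced.S[j, kk]
            if s.reduced.var_spec is not None:
                row["knot1"], row["knot2"] = s.reduced.var_spec.internal_knots
                row["boundary_hi"] = s.reduced.var_spec.boundary_knots[1]
            fits.append(row)
        pd.DataFrame(fits).to_csv(out / f"city_fits_{t}.csv", index=False)
        reg = r["regional_attribution"]
        rows.append({"level": "region", "type": t, "outcome": "all",
                     "AN": reg["an"], "AF_pct": reg["af_pct"],
                     "nsim": cfg.nsim, "seed": cfg.seed, **stamp})
        for s, a in zip(r["stage_ones"], r["city_attribution"]):
            rows.append({"level": s.city_id, "type": t, "outcome": "all",
                         "AN": a.an, "AF_pct": a.af_pct, "eCI_lo": a.eci_low,
                         "eCI_hi": a.eci_high, "nsim": a.nsim, "seed": a.seed,
                         **stamp})
    if rows:
        pd.DataFrame(rows).to_csv(out / "attribution.csv", index=False)


def run_effect_modification(stage_ones, attributes: pd.DataFrame,
                            predictors=None, population_split: bool = True) -> pd.DataFrame:
    """Univariable meta-regressions per city attribute plus one multivariable
    model excluding latitude/longitude; Wald test and Q/I^2 per model."""
    etas = np.stack([s.reduced.eta for s in stage_ones])
    Ss = np.stack([s.reduced.S for s in stage_ones])
    attrs = attributes.set_index("city_id").loc[[s.city_id for s in stage_ones]]
    if predictors is None:
        predictors = ["climate_class", "gdp_per_capita", "summer_mean_temp",
                      "summer_temp_range", "population", "latitude", "longitude"]
    work = attrs.copy()
    if population_split and "population" in work:
        med = work["population"].median()
        work["population"] = np.where(work["population"] > med, "large", "small")
    rows = []
    for name in predictors:
        X, names = meta.design_matrix({name: work[name].to_numpy()},
                                      k=len(stage_ones))
        fit = meta.mvmeta_reml(etas, Ss, X=X, names=names)
        W, df, p = meta.wald_test(fit, name)
        het = meta.heterogeneity(etas, Ss, X=X)
        rows.append({"model": "univariable", "predictor": name, "wald": W,
                     "df": df, "p": p, "Q": het.Q, "I2": het.I2})
    multi = [p for p in predictors if p not in ("latitude", "longitude")]
    X, names = meta.design_matrix({p: work[p].to_numpy() for p in multi},
                                  k=len(stage_ones))
    if len(stage_ones) > X.shape[1]:
        fitm = meta.mvmeta_reml(etas, Ss, X=X, names=names)
        hetm = meta.heterogeneity(etas, Ss, X=X)
        for p in multi:
            W, df, pv = meta.wald_test(fitm, p)
            rows.append({"model": "multivariable", "predictor": p, "wald": W,
                         "df": df, "p": pv, "Q": hetm.Q, "I2": hetm.I2})
    return pd.DataFrame(rows)
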