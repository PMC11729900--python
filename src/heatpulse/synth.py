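"""Synthetic multi-city climate and mortality generator.

The generator produces the two ingredients of a two-stage heatwave-mortality
study with a *known* truth, so that every downstream stage (exposure
detection, first-stage distributed-lag fits, pooling, attribution) can be
validated end to end:

* hourly temperature with a smooth seasonal cycle, a diurnal cycle peaking
  mid-afternoon, AR(1) day-level anomalies (which produce multi-day runs of
  hot days and nights) and optional extra night warmth to tune the mix of
  daytime-only, nighttime-only and compound heatwaves;
* overdispersed daily death counts whose log-mean contains a known
  distributed-lag contribution of the CEHWI exposure per heatwave type, a
  smooth seasonal term, day-of-week and year effects.

Counts are drawn negative-binomially with mean mu and variance phi * mu,
matching at the moment level the quasi-Poisson variance assumption of the
estimation stage.  A multi-city panel shares one true exposure-response
surface up to an independent per-city scale perturbation (the between-city
heterogeneity), with per-city random streams split off a master seed by a
counter-based rule so the panel is reproducible independent of city order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import HW_TYPES

MAX_LAG = 6
_NS_PER_DAY = 86_400_000_000_000


def default_seasonal_curve(doy: np.ndarray) -> np.ndarray:
    """Annual-cycle daily mean (deg C): 16 +- 11, peaking around July 15."""
    return 16.0 + 11.0 * np.cos(2.0 * np.pi * (np.asarray(doy) - 196.0) / 365.25)


@dataclass(frozen=True)
class ClimateScenario:
    """Parameters of the hourly temperature generator.

    years
        number of full calendar years simulated (>= 2).
    seasonal_mean_curve
        smooth annual cycle of the daily mean (deg C) as a function of
        day-of-year.
    diurnal_amplitude
        half-range (deg C) of the within-day cycle (peak mid-afternoon).
    anomaly_sd, anomaly_ar1
        standard deviation (deg C) and lag-1 autocorrelation of the AR(1)
        day-level anomaly shared by all hours of a day.
    day_night_anomaly_frac
        sd of an independent AR(1) day-night *contrast* anomaly, as a
        fraction of ``anomaly_sd``; added to daytime hours and subtracted
        from nighttime/evening hours (half each).  It decorrelates Tmax from
        Tmin, producing daytime-only and nighttime-only events alongside
        compound ones; 0 makes hot days and hot nights coincide.
    hour_noise_sd
        sd (deg C) of independent hour-level noise.
    night_warming_offset
        deg C added to nighttime and evening hours; raising it shifts events
        from daytime-only towards compound/nighttime types.
    """

    years: int = 10
    seasonal_mean_curve: Callable[[np.ndarray], np.ndarray] = default_seasonal_curve
    diurnal_amplitude: float = 4.0
    anomaly_sd: float = 3.0
    anomaly_ar1: float = 0.7
    hour_noise_sd: float = 0.5
    day_night_anomaly_frac: float = 1.2
    night_warming_offset: float = 0.0
    start_year: int = 1996
    seed: int = 0

    def __post_init__(self):
        if self.years < 2:
            raise ValueError("years must be >= 2")
        if not 0.0 <= self.anomaly_ar1 < 1.0:
            raise ValueError("anomaly_ar1 must be in [0, 1)")
        for name in ("diurnal_amplitude", "anomaly_sd", "hour_noise_sd",
                     "night_warming_offset"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.anomaly_sd < 0 or self.hour_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def generate_hourly_temperature(scenario: ClimateScenario) -> pd.Series:
    """Simulate one city's hourly temperature for ``scenario.years`` full
    calendar years.  Deterministic given the scenario seed."""
    rng = np.random.default_rng(scenario.seed)
    start = pd.Timestamp(year=scenario.start_year, month=1, day=1)
    end = pd.Timestamp(year=scenario.start_year + scenario.years - 1,
                       month=12, day=31, hour=23)
    idx = pd.date_range(start, end, freq="h")
    n_days = len(idx) // 24
    doy = idx.dayofyear.to_numpy()
    hours = idx.hour.to_numpy()

    def ar1(sd, rho, eps):
        out = np.empty(len(eps))
        if sd == 0.0:
            out[:] = 0.0
            return out
        out[0] = sd * eps[0]
        innov_sd = sd * np.sqrt(1.0 - rho**2)
        for t in range(1, len(eps)):
            out[t] = rho * out[t - 1] + innov_sd * eps[t]
        return out

    rho = scenario.anomaly_ar1
    anom = ar1(scenario.anomaly_sd, rho, rng.standard_normal(n_days))
    contrast = ar1(scenario.day_night_anomaly_frac * scenario.anomaly_sd, rho,
                   rng.standard_normal(n_days))

    seasonal = np.asarray(scenario.seasonal_mean_curve(doy), dtype=float)
    diurnal = scenario.diurnal_amplitude * np.cos(2.0 * np.pi * (hours - 15) / 24.0)
    night = (hours < 6) | (hours >= 18)
    sign = np.where(night, -0.5, 0.5)
    temp = (
        seasonal
        + diurnal
        + np.repeat(anom, 24)
        + np.repeat(contrast, 24) * sign
        + scenario.night_warming_offset * night
    )
    if scenario.hour_noise_sd > 0:
        temp = temp + scenario.hour_noise_sd * rng.standard_normal(len(idx))
    return pd.Series(temp, index=idx, name="temp_c")


def generate_humidity(dates: pd.DatetimeIndex, seed: int, mean: float = 70.0,
                      sd: float = 10.0, ar1: float = 0.8) -> pd.Series:
    """Bounded AR(1) daily relative humidity in [20, 100] percent."""
    rng = np.random.default_rng(seed)
    n = len(dates)
    x = np.empty(n)
    innov = rng.standard_normal(n) * sd * np.sqrt(1 - ar1**2)
    x[0] = mean + sd * rng.standard_normal()
    for t in range(1, n):
        x[t] = mean + ar1 * (x[t - 1] - mean) + innov[t]
    return pd.Series(np.clip(x, 20.0, 100.0), index=dates, name="rh")


# ---------------------------------------------------------------------------
# true exposure-response surfaces

def lag_weights(decay: float = 0.6, max_lag: int = MAX_LAG) -> np.ndarray:
    """Geometric lag weights normalised to sum to one."""
    w = decay ** np.arange(max_lag + 1)
    return w / w.sum()


def make_surface(cumulative: Callable[[np.ndarray], np.ndarray],
                 decay: float = 0.6) -> Callable:
    """Distribute a cumulative log-RR curve over lags 0-6 with geometric
    decay; the returned ``f(x, lag)`` satisfies ``sum_l f(x, l) =
    cumulative(x)`` and ``f(0, l) = 0`` provided ``cumulative(0) = 0``."""
    w = lag_weights(decay)

    def f(x, lag):
        return np.asarray(cumulative(np.asarray(x, dtype=float))) * w[np.asarray(lag)]

    return f


def linear_surface(slope: float, decay: float = 0.6) -> Callable:
    return make_surface(lambda x: slope * x, decay)


def threshold_surface(slope: float, knee: float, decay: float = 0.6) -> Callable:
    """Hockey-stick cumulative curve: flat below ``knee``, linear above —
    a nonlinear truth of the kind seen for daytime/nighttime events."""
    return make_surface(lambda x: slope * np.clip(x - knee, 0.0, None), decay)


def null_surface() -> Callable:
    return make_surface(lambda x: np.zeros_like(np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class MortalityScenario:
    """Parameters of the daily death-count generator.

    ``true_surface`` maps heatwave type -> f(cehwi, lag) giving the log-RR
    contribution of exposure ``cehwi`` at lag ``lag`` (f(0, l) must be 0);
    ``overdispersion`` is the variance inflation factor phi >= 1 of the
    negative-binomial counts (phi = 1 reduces to Poisson).
    """

    baseline_daily_deaths: float = 50.0
    true_surface: Mapping[str, Callable] = field(
        default_factory=lambda: {t: null_surface() for t in HW_TYPES}
    )
    season_effect_amplitude: float = 0.1
    dow_effects: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.02, 0.02)
    year_trend: float = 0.0
    overdispersion: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if not self.baseline_daily_deaths > 0:
            raise ValueError("baseline_daily_deaths must be > 0")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries")


def mortality_log_mean(cehwi: pd.DataFrame, scenario: MortalityScenario) -> pd.Series:
    """Deterministic log-mean of daily deaths given per-type CEHWI series."""
    idx = cehwi.index
    doy = idx.dayofyear.to_numpy()
    dow = idx.dayofweek.to_numpy()
    year = idx.year.to_numpy()
    log_mu = np.full(len(idx), np.log(scenario.baseline_daily_deaths))
    log_mu += scenario.season_effect_amplitude * np.cos(
        2.0 * np.pi * (doy - 196) / 365.25
    )
    log_mu += np.asarray(scenario.dow_effects)[dow]
    log_mu += scenario.year_trend * (year - year.min())
    lags = np.arange(MAX_LAG + 1)
    for t in HW_TYPES:
        f = scenario.true_surface.get(t)
        if f is None:
            continue
        x = cehwi[f"cehwi_{t}"].to_numpy(dtype=float)
        for l in lags:
            xl = np.concatenate([np.zeros(l), x[: len(x) - l]])  # zero history pre-start
            log_mu += np.asarray(f(xl, l), dtype=float)
    return pd.Series(log_mu, index=idx, name="log_mu")


def generate_mortality(cehwi: pd.DataFrame, scenario: MortalityScenario,
                       calendar: pd.DataFrame | None = None) -> pd.Series:
    """Draw daily death counts for the days of ``cehwi``.

    ``calendar`` (if given) must align with ``cehwi``; it is accepted to make
    the exposure/label pairing explicit at call sites.  Counts are negative
    binomial with mean mu and variance phi * mu.
    """
    if calendar is not None and not calendar.index.equals(cehwi.index):
        raise ValueError("heatwave calendar and CEHWI series are misaligned")
    rng = np.random.default_rng(scenario.seed)
    mu = np.exp(mortality_log_mean(cehwi, scenario).to_numpy())
    phi = scenario.overdispersion
    if phi == 1.0:
        counts = rng.poisson(mu)
    else:
        # NB(r, p): mean r(1-p)/p = mu, var mu/p = phi*mu  =>  p = 1/phi
        r = mu / (phi - 1.0)
        counts = rng.negative_binomial(r, 1.0 / phi)
    return pd.Series(counts, index=cehwi.index, name="deaths")


# ---------------------------------------------------------------------------
# multi-city panels

@dataclass
class CityData:
    city_id: str
    hourly: pd.Series
    humidity: pd.Series
    deaths: pd.Series
    attributes: dict
    surface_scale: float  # multiplier on the common true surface
    cehwi: pd.DataFrame | None = None  # cached exposure used for the truth


@dataclass
class SyntheticPanel:
    cities: list
    heterogeneity_sd: float
    climate: ClimateScenario
    mortality: MortalityScenario

    def __iter__(self):
        return iter(self.cities)

    def __len__(self):
        return len(self.cities)


_CLIMATE_CLASSES = ("Cfa", "Cwa", "Dwa")


def _scaled_surface(surface: Mapping[str, Callable], scale: float):
    return {t: (lambda f: (lambda x, l: scale * np.asarray(f(x, l))))(f)
            for t, f in surface.items()}


def make_panel(n_cities: int, climate: ClimateScenario,
               mortality: MortalityScenario, heterogeneity_sd: float = 0.0,
               seed: int = 0, population_effect: float = 0.0,
               exposure_fn: Callable | None = None) -> SyntheticPanel:
    """Generate an aligned multi-city panel.

    Each city gets independent random streams split off the master ``seed``
    with :class:`numpy.random.SeedSequence` (counter-based, so reproducible
    regardless of generation order), a true surface equal to the common one
    scaled by ``1 + delta_i`` with ``delta_i ~ N(0, heterogeneity_sd)``, and
    random city attributes.  ``population_effect`` adds a log-population
    (standard-normal score) contribution to the surface scale, giving panels
    with a known effect modifier.  ``exposure_fn`` maps an hourly series to a
    per-type CEHWI frame; it defaults to the package's own detection chain
    and is injectable so the generator stays decoupled from it in tests.
    """
    if n_cities < 1:
        raise ValueError("n_cities must be >= 1")
    if exposure_fn is None:
        from .pipeline import exposure_chain

        exposure_fn = lambda hourly: exposure_chain(hourly)[2]
    master = np.random.SeedSequence(seed)
    city_seeds = master.spawn(n_cities)
    cities = []
    for i, ss in enumerate(city_seeds):
        child = ss.generate_state(6) % (2**31)
        rng = np.random.default_rng(ss.spawn(1)[0])
        delta = heterogeneity_sd * rng.standard_normal()
        log_pop = np.log(3.3e6) + 0.8 * rng.standard_normal()
        pop_score = (log_pop - np.log(3.3e6)) / 0.8
        scale = 1.0 + delta + population_effect * pop_score
        cs = dataclasses.replace(climate, seed=int(child[0]))
        hourly = generate_hourly_temperature(cs)
        cehwi = exposure_fn(hourly)
        ms = dataclasses.replace(
            mortality, seed=int(child[1]),
            true_surface=_scaled_surface(mortality.true_surface, scale),
        )
        deaths = generate_mortality(cehwi, ms)
        humidity = generate_humidity(cehwi.index, int(child[2]))
        summer = hourly[hourly.index.month.isin((6, 7, 8))]
        attributes = {
            "latitude": float(22 + 23 * rng.random()),
            "longitude": float(104 + 37 * rng.random()),
            "population": float(np.exp(log_pop)),
            "gdp_per_capita": float(np.exp(9.5 + 0.6 * rng.standard_normal())),
            "climate_class": _CLIMATE_CLASSES[int(rng.integers(len(_CLIMATE_CLASSES)))],
            "summer_mean_temp": float(summer.mean()),
            "summer_temp_range": float(summer.max() - summer.min()),
        }
        cities.append(CityData(
            city_id=f"city{i:02d}", hourly=hourly, humidity=humidity,
            deaths=deaths, attributes=attributes, surface_scale=float(scale),
            cehwi=cehwi,
        ))
    return SyntheticPanel(cities=cities, heterogeneity_sd=heterogeneity_sd,
                          climate=climate, mortality=mortality)


def write_panel_csv(panel: SyntheticPanel, outdir) -> None:
    """Write per-city hourly climate and daily series plus the attribute
    table as plain CSV."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in panel:
        c.hourly.rename("temp_c").to_csv(
            outdir / f"{c.city_id}_hourly.csv", index_label="timestamp")
        daily = pd.DataFrame({"deaths": c.deaths, "rh": c.humidity})
        daily.to_csv(outdir / f"{c.city_id}_daily.csv", index_label="date")
        rows.append({"city_id": c.city_id, **c.attributes})
    pd.DataFrame(rows).to_csv(outdir / "attributes.csv", index=False)
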