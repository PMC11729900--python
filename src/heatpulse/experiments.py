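"""Reusable calibration and recovery experiments.

Each function runs a self-contained simulation study against the package's
own synthetic generator and returns summary numbers (coverage rates, error
rates, calibration fractions).  They are used by the test suite and by the
reproduction script; all randomness flows from an explicit seed.

Study conditions follow the synthetic defaults: 10-year single-city series
with a baseline of 50 deaths/day for first-stage checks, and a 28-city panel
for the pooling checks.  The truths differ by purpose: the first-stage
recovery uses a super-linear (quadratic) cumulative curve with geometrically
decaying lag weights — a compound-heatwave-like shape that is *not* inside
the spline span, so coverage includes approximation error at single-city CI
widths; the pooled check uses a linear curve with uniform lag weights, which
every natural cubic exposure basis and intercepted lag basis represents
exactly, so that the much narrower pooled CIs isolate the second-stage
machinery rather than spline approximation.
"""

from __future__ import annotations

import numpy as np

from . import attribution as attr_mod
from . import dlnm, meta, pipeline, synth

QUADRATIC_SLOPE = 0.03
QUADRATIC_CURV = 0.012
LINEAR_SLOPE = 0.08


def quadratic_cumulative(x):
    x = np.asarray(x, dtype=float)
    return QUADRATIC_SLOPE * x + QUADRATIC_CURV * x**2


def linear_cumulative(x):
    return LINEAR_SLOPE * np.asarray(x, dtype=float)


def _surface(cumulative, decay):
    return {"dhw": synth.null_surface(), "nhw": synth.null_surface(),
            "chw": synth.make_surface(cumulative, decay=decay)}


def _simulate_city(seed_triplet, surface, years=10, baseline=50.0,
                   overdispersion=1.2):
    s_clim, s_mort, s_hum = (int(s) for s in seed_triplet)
    climate = synth.ClimateScenario(years=years, seed=s_clim)
    hourly = synth.generate_hourly_temperature(climate)
    _, cal, cehwi = pipeline.exposure_chain(hourly)
    ms = synth.MortalityScenario(baseline_daily_deaths=baseline,
                                 true_surface=surface,
                                 overdispersion=overdispersion, seed=s_mort)
    deaths = synth.generate_mortality(cehwi, ms)
    humidity = synth.generate_humidity(cehwi.index, s_hum)
    city = synth.CityData("sim", hourly, humidity, deaths, {}, 1.0)
    return city, cehwi


def first_stage_recovery(n_reps=100, seed=0, years=10, baseline=50.0,
                         n_grid=10) -> dict:
    """Pointwise 95% CI coverage of the true overall cumulative curve by
    single-city first-stage fits under a known nonlinear distributed-lag
    truth.  Returns the pooled coverage over replicates x grid points."""
    ss = np.random.SeedSequence(seed)
    surface = _surface(quadratic_cumulative, decay=0.6)
    cfg = pipeline.RunConfig(nsim=100)
    hits = total = fitted = 0
    for child in ss.spawn(n_reps):
        city, cehwi = _simulate_city(child.generate_state(3) % (2**31),
                                     surface, years=years, baseline=baseline)
        s1 = pipeline.fit_city_type(city, cehwi, "chw", cfg)
        if s1 is None:
            continue
        fitted += 1
        x = s1.exposure
        grid = np.linspace(0.2, float(np.quantile(x[x > 0], 0.99)), n_grid)
        curve = dlnm.predict_overall_curve(s1.reduced, grid)
        truth = quadratic_cumulative(grid)
        ok = ((np.log(curve["rr_low"]) <= truth)
              & (truth <= np.log(curve["rr_high"])))
        hits += int(ok.sum())
        total += len(ok)
    return {"coverage": hits / total if total else float("nan"),
            "n_fitted": fitted, "n_reps": n_reps}


def pooled_panel_study(n_reps=10, n_cities=28, seed=0, years=10,
                       baseline=50.0, heterogeneity_sd=0.0, n_grid=10) -> dict:
    """Two-stage pooling on synthetic panels with a common in-span truth:
    pooled-curve CI coverage of the truth and the per-replicate I^2 under
    zero (or given) between-city heterogeneity."""
    surface = _surface(linear_cumulative, decay=1.0)
    cfg = pipeline.RunConfig(nsim=100)
    ss = np.random.SeedSequence(seed)
    covers, i2s, ks = [], [], []
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        climate = synth.ClimateScenario(years=years)
        ms = synth.MortalityScenario(baseline_daily_deaths=baseline,
                                     true_surface=surface, overdispersion=1.2)
        panel = synth.make_panel(
            n_cities, climate, ms, heterogeneity_sd=heterogeneity_sd,
            seed=rep_seed,
            exposure_fn=lambda h: pipeline.exposure_chain(h)[2])
        stage = []
        for c in panel:
            s1 = pipeline.fit_city_type(c, c.cehwi, "chw", cfg)
            if s1 is not None:
                stage.append(s1)
        etas = np.stack([s.reduced.eta for s in stage])
        Ss = np.stack([s.reduced.S for s in stage])
        fit = meta.mvmeta_reml(etas, Ss)
        het = meta.heterogeneity(etas, Ss)
        spec = pipeline._pooled_var_spec(stage)
        grid = np.linspace(0.2, spec.boundary_knots[1], n_grid)
        curve = meta.pooled_curve(fit, spec, grid)
        truth = linear_cumulative(grid)
        ok = ((np.log(curve["rr_low"]) <= truth)
              & (truth <= np.log(curve["rr_high"])))
        covers.append(float(ok.mean()))
        i2s.append(het.I2)
        ks.append(len(stage))
    return {"coverage": float(np.mean(covers)), "per_rep_coverage": covers,
            "i2": i2s, "frac_i2_below_10": float(np.mean(np.array(i2s) < 10)),
            "k_fitted": ks, "n_reps": n_reps}


def null_attribution_coverage(n_reps=100, seed=0, years=10, baseline=50.0,
                              nsim=500) -> dict:
    """Fraction of null-truth replicates whose attributable-fraction
    empirical CI contains 0."""
    surface = _surface(lambda x: np.zeros_like(np.asarray(x, float)),
                       decay=1.0)
    cfg = pipeline.RunConfig(nsim=nsim)
    ss = np.random.SeedSequence(seed)
    contains = fitted = 0
    for child in ss.spawn(n_reps):
        trip = child.generate_state(4) % (2**31)
        city, cehwi = _simulate_city(trip[:3], surface, years=years,
                                     baseline=baseline)
        s1 = pipeline.fit_city_type(city, cehwi, "chw", cfg)
        if s1 is None:
            continue
        fitted += 1
        res = attr_mod.attributable_fraction(
            s1.deaths_summer, s1.exposure, s1.reduced,
            attr_mod.AttributionConfig(nsim=nsim, seed=int(trip[3])))
        contains += int(res.eci_low <= 0.0 <= res.eci_high)
    return {"containment": contains / fitted if fitted else float("nan"),
            "n_fitted": fitted, "n_reps": n_reps}


def wald_type_i_error(n_reps=500, seed=0, k=28, alpha=0.05) -> dict:
    """Rejection rate of the Wald test for a standard-normal meta-predictor
    that truly has no effect, at realistic first-stage covariance scales."""
    rng = np.random.default_rng(seed)
    v = 3
    S0 = np.array([[0.008, -0.004, 0.034],
                   [-0.004, 0.002, -0.020],
                   [0.034, -0.020, 0.360]])
    psi = 0.002 * np.eye(v)
    rej = 0
    for _ in range(n_reps):
        x = rng.standard_normal(k)
        X = np.column_stack([np.ones(k), (x - x.mean()) / x.std()])
        eta = (np.array([LINEAR_SLOPE, 0.0, 0.0])
               + rng.multivariate_normal(np.zeros(v), S0 + psi, size=k))
        fit = meta.mvmeta_reml(eta, np.tile(S0, (k, 1, 1)), X=X,
                               names=["intercept", "z"])
        _, _, p = meta.wald_test(fit, "z")
        rej += p < alpha
    return {"rejection_rate": rej / n_reps, "n_reps": n_reps}


def threshold_calibration(years=30, seed=0, percentile=90.0) -> dict:
    """Empirical exceedance rate of the calendar-day threshold on a long
    stationary series (nominal rate: 100 - percentile)."""
    from . import exposure

    climate = synth.ClimateScenario(years=years, seed=seed)
    hourly = synth.generate_hourly_temperature(climate)
    daily = exposure.daily_summaries(hourly)
    thr = exposure.calendar_thresholds(daily, percentile=percentile)
    flags = exposure.exceedance_flags(daily, thr)
    return {"tmax_rate": float(flags["hmax"].mean()),
            "tmin_rate": float(flags["hmin"].mean()),
            "nominal": (100.0 - percentile) / 100.0, "n_days": len(daily)}
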