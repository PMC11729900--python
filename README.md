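# heatpulse

Two-stage analysis of heatwave-related mortality from hourly temperature,
for environmental-epidemiology researchers who want a continuous measure of
heatwave intensity instead of the usual 0/1 heatwave indicator.

Heatwaves are detected as runs of at least two consecutive days whose daily
maximum and/or minimum temperature exceed calendar-day 90th-percentile
thresholds (15-day sliding window over the reference years), and are
classified as daytime-only (hot days, cool nights), nighttime-only, or
day–night compound events. Each event day then carries a **Cumulative
Excess Heatwave Index** (CEHWI): the mean hourly exceedance above the
threshold over the exceeding hours of the type's diel period,

    CEHWI_ig = Σ_j (t_jg − Thr_ig) · 1[t_jg > Thr_ig] / n_ig .

The health model is the standard two-stage multi-city design:

1. **City level** — quasi-Poisson regression of daily deaths on a
   distributed-lag non-linear cross-basis of CEHWI (natural cubic spline in
   exposure, knots at the 50th/90th percentiles; natural cubic spline over
   lags 0–6, 3 df), adjusting for day-of-season ns(4), relative humidity
   ns(3), year and day-of-week indicators. The fit is reduced to the
   overall cumulative association η with covariance S.
2. **Pooling** — multivariate random-effects meta-regression of the (η, S)
   pairs by REML, giving pooled exposure–response curves RR(x) relative to
   CEHWI = 0, Cochran Q / I² heterogeneity statistics, Wald tests for
   city-level effect modifiers, and per-city BLUPs.
3. **Burden** — backward attributable deaths and fractions from the BLUP
   curves, with Monte-Carlo empirical 95% CIs from multivariate-normal
   coefficient draws.

A fully seeded synthetic generator (multi-city hourly climate with AR(1)
anomalies plus overdispersed death counts with a known distributed-lag
truth) makes the whole chain testable end to end; real studies of this
design rely on restricted mortality registries, so the bundled data are
synthetic by construction.

## Worked example

```python
import numpy as np
from heatpulse import pipeline

cfg = pipeline.RunConfig(n_cities=20, years=10, seed=1,
                         heterogeneity_sd=0.1, nsim=1000)
res = pipeline.run_full(cfg)
for t, r in res["types"].items():
    if "skipped" in r:
        continue
    het = r["heterogeneity"]
    reg = r["regional_attribution"]
    rr_top = r["curve"]["rr"].iloc[-1]
    print(f"{t}: k={r['n_cities']:2d}  RR(boundary)={rr_top:.3f}  "
          f"I2={het.I2:.1f}%  AF={reg['af_pct']:.3f}%")
```

Output (seed 1):

```
dhw: k= 3  RR(boundary)=0.931  I2=0.0%  AF=0.128%
nhw: k=11  RR(boundary)=1.293  I2=20.1%  AF=0.413%
chw: k=19  RR(boundary)=1.368  I2=0.0%  AF=0.579%
```

Each line is one heatwave type: `k` cities had enough event days for a
stable city-level fit (compound events are the most frequent in the default
climate, so nearly all cities contribute there, while daytime-only events
are sparse enough that only three cities support a fit — their pooled curve
is accordingly noisy), `RR(boundary)` is the pooled relative risk at the
upper end of the exposure range (the panel-mean 99th CEHWI percentile)
versus non-heatwave days, `I2` the share of between-city variation in the
pooled curves attributable to heterogeneity, and `AF` the percentage of all
summer deaths attributable to that heatwave type. Under the default
synthetic truth (cumulative log-RR 0.05 per unit CEHWI, 10% between-city
scale heterogeneity) compound heatwaves carry the largest burden because
they are both the most frequent and the most intense type.

The command line mirrors the library:

```bash
heatpulse simulate --n-cities 4 --years 10 --out data/
heatpulse detect --hourly-csv data/city00_hourly.csv --out events.csv
heatpulse run-all --out results/ --seed 1
heatpulse effect-mod --type chw
```

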