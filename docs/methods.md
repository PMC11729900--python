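# Methods

`heatpulse` implements a two-stage time-series design for estimating the
mortality burden of heatwaves from hourly temperature, using a continuous
exposure index rather than the conventional binary heatwave indicator.

## Exposure: heatwave types and the CEHWI

A day is *hot* when its Tmax reaches the calendar-day threshold, a night is
hot when Tmin does. Thresholds are sample percentiles (default the 90th,
linear-interpolation "type 7" quantiles) of the pooled distribution over a
15-day window centred on each calendar day across all reference years, so
the definition is relative to the local seasonal climatology; Feb 29 is
pooled with Feb 28. Days with missing hours are excluded from threshold
estimation. Maximal runs of at least `min_duration` (default 2) consecutive
days of one joint-flag pattern become events:

* **DHW** — hot days without hot nights (Tmax ≥ thr, Tmin < thr),
* **NHW** — hot nights without hot days,
* **CHW** — both exceed (compound).

Runs are split where the pattern changes; the "without preceding hot
nights" clause is implemented as day-level mutual exclusivity of the joint
flags, one consistent reading of the definition.

On an event day the **Cumulative Excess Heatwave Index** is the mean hourly
exceedance over exceeding hours of the type's diel period:

CEHWI_ig = Σ_j (t_jg − Thr_ig) · 1[t_jg > Thr_ig] / n_ig

with the hours restricted to daytime (DHW, against the Tmax threshold),
nighttime + evening (NHW, against Tmin) or the whole day (CHW, against
Tmean), and n_ig the number of strictly exceeding hours (0 exceeding hours,
or a non-event day, gives CEHWI 0). The diel partition defaults to fixed
06:00/18:00 sunrise/sunset for synthetic work; `solar_day_partition`
computes them from latitude/longitude/date with the NOAA solar-position
equations when a real location is analysed. Units: °C of mean hourly
exceedance ("degree per exceeding hour").

## First stage: city-level distributed-lag model

Daily deaths Y_g are modelled log-linearly with a quasi-Poisson variance
(Var = φ·mean, φ from the Pearson statistic; fitting via iteratively
reweighted least squares through `statsmodels` GLM). The exposure enters as
a cross-basis over lags 0–6 days: natural cubic spline in the exposure
dimension (2 internal knots at the 50th/90th percentiles of the city's
*positive* CEHWI values — percentiles over all days would pin both knots at
0 — with the upper boundary knot at the 99th percentile, extreme days
handled by the natural linear extrapolation) times a natural cubic spline
in the lag dimension (3 df: intercept + basis with one internal knot at the
log-midpoint of lags 1–6). The lag intercept matters: without it an effect
constant across lags is outside the model span. Confounders: day-of-season
natural spline (4 df on days since June 1), relative humidity natural
spline (3 df, lag 0), year indicators, day-of-week indicators; optional
same-day PM10/O3 as linear terms. One model is fitted per heatwave type
(that type's CEHWI, zero off events), matching separately reported
type-specific curves. Analysis days are June 1–Aug 31; exposure histories
come from the year-round series so early-June lags are defined.

Summing the lag basis over lags 0–6 reduces the fitted coefficient matrix
exactly to the overall cumulative association: a coefficient vector η
(dimension 3) with covariance S — curves are reported as
RR(x) = exp{(z(x) − z(0))'η} relative to non-event days (CEHWI = 0), with
delta-method CIs. The reduction is linear, so the overall cumulative
log-RR equals the sum of the seven lag-specific log-RRs identically (tested
to 1e−10).

## Second stage: REML meta-regression, heterogeneity, BLUPs

City vectors η_i ~ MVN(X_i B, S_i + Ψ) are pooled by restricted maximum
likelihood: B profiled out by GLS, the unstructured between-city covariance
Ψ parameterised by its Cholesky factor (log-diagonal) and optimised by
L-BFGS from a moment-based start (tolerance 1e−6 on the restricted
log-likelihood; Ψ = 0 is also evaluated explicitly since REML often sits on
that boundary). Pooled curves use the intercept-level coefficients with the
exposure basis rebuilt at panel-average knots and the boundary at the
simple mean of city-specific 99th CEHWI percentiles (population weighting
would be an alternative; simple means are used). Heterogeneity:
Q = Σ r_i' S_i⁻¹ r_i from fixed-effects (Ψ=0) GLS residuals,
df = (k − m)·v, I² = max(0, (Q − df)/Q)·100. Meta-predictors (climate
class as indicator contrasts, continuous predictors standardised,
population optionally split at the panel median) are tested by Wald
chi-square on their v-coefficient blocks; the multivariable model excludes
latitude and longitude to avoid multicollinearity. BLUPs shrink each city
toward its fixed-effect prediction, BLUP_i = X_iB̂ + Ψ̂(S_i+Ψ̂)⁻¹(η_i −
X_iB̂), with conditional covariance plus propagated fixed-effect
uncertainty.

## Attribution

The burden is computed backward: deaths on day g are attributed to the past
week's exposure. With only the reduced curve available after pooling, the
day's cumulative log-RR is the lag-average of the overall curve at each
lagged exposure, c_g = (1/7)Σ_l f(x_{g−l}) — the standard device for
reduced coefficients, exact under constant exposure across the window.
Then AN_g = d_g(1 − e^{−c_g}), AF = ΣAN / Σdeaths × 100 with the
denominator over *all* summer deaths. Negative contributions from
protective curve regions are kept (truncation at zero is a config switch).
Regional figures pool counts (ΣAN/Σdeaths), not city AFs. Empirical 95%
CIs redraw the coefficients from MVN(BLUP, BLUP covariance) `nsim` times
(default 5000) and recompute the AF per draw; everything is seeded.

## Synthetic data

The generator produces the study's ingredients with a known truth:

* **Temperature**: seasonal cycle (default 16 ± 11 °C peaking July 15) +
  diurnal cycle (±4 °C, peak 15:00) + AR(1) day-level anomalies (sd 3 °C,
  ρ = 0.7) + an independent AR(1) day–night *contrast* anomaly (sd = 1.2 ×
  anomaly sd, added half to daytime and subtracted half from nighttime
  hours) + hourly noise (sd 0.5 °C). The contrast term is what decorrelates
  Tmax from Tmin: without it hot days and hot nights always coincide and
  only compound events occur. A constant `night_warming_offset` shifts the
  night climatology but — because thresholds are calendar-relative — does
  not by itself change the type mix. The default contrast fraction 1.2
  yields a realistic mix (compound events most frequent, both single types
  present).
* **Mortality**: counts are negative binomial with mean μ and variance φμ
  (default φ = 1.2; φ = 1 reduces to Poisson), matching the estimator's
  quasi-Poisson variance assumption at the moment level. log μ = baseline
  (default 50/day) + known per-type distributed-lag surfaces applied to the
  realised CEHWI + seasonal cosine (amplitude 0.1) + day-of-week offsets +
  optional linear year trend. Surface factories provide linear,
  hockey-stick and null cumulative curves distributed over lags with
  geometric weights.
* **Panels**: per-city streams split off a master seed with
  `numpy.random.SeedSequence` (counter-based, order-independent); city
  surfaces are the common surface scaled by 1 + δ_i, δ_i ~ N(0,
  heterogeneity_sd), optionally plus a log-population effect for
  effect-modification studies. Humidity is bounded AR(1) in [20, 100]% and
  enters the truth not at all by default, so humidity adjustment is a
  pure-noise covariate. Attributes (latitude, longitude, population, GDP,
  climate class, summer mean/range) are drawn from East-Asian-city-like
  ranges.

What the generator does **not** emulate: spatial correlation between
cities, real city climates, demographic structure, exposure measurement
error (the fitted exposure is exactly the generating exposure), or
reporting artefacts in death counts. Passing recovery tests therefore
demonstrate correctness of the estimation chain under the model's own
assumptions, not robustness to the misspecifications of real data.

## Validation design and numerical choices

The test suite validates each stage against an independent oracle:
brute-force subsequence scanning for event detection, closed-form type-7
quantiles for thresholds, an independent B-spline-with-natural-constraints
construction for the spline basis, grid search of the univariate restricted
likelihood and the univariate shrinkage closed form for REML/BLUPs, and
closed-form attributable fractions under constant risk.

Two simulation studies check estimator calibration at deliberately
different truths. Single-city recovery uses a super-linear quadratic
cumulative curve (0.03x + 0.012x²) with geometric lag decay — *outside*
the spline span, so single-city CI coverage (~92–97%) includes
approximation error at realistic CI widths. The 28-city pooling study uses
a linear curve with uniform lag weights — exactly representable in every
exposure basis — so the much narrower pooled CIs isolate the second-stage
machinery (measured coverage ~93–100%).

A known limitation: I² is a noisy statistic. With k ≈ 27 cities and v = 3
the heterogeneity Q has ≈ 78 degrees of freedom, and even a perfectly
calibrated Q ~ χ²₇₈ exceeds the I² = 10 point in roughly a quarter of
null-heterogeneity replicates; finite-sample conservativeness of the
first-stage covariances typically deflates Q well below that (median I² is
0 in our null panels), but occasional replicates with one heavy-tailed
city fit still push I² to 10–25 even with no true heterogeneity. Single
I² values near 10–20 on ~28-city panels should therefore not be read as
evidence of real between-city heterogeneity.

Problem sizes used by the bundled studies: 10-year single-city series
(≈ 920 summer days) with baseline 50 deaths/day for first-stage checks;
28-city panels for pooling checks (10 replicates); 500 replicates for the
Wald test size; 30 years for threshold calibration; 60–100 replicates for
coverage studies. IRLS tolerance 1e−8 (max 50 iterations); REML tolerance
1e−6; all-zero outcomes, rank-deficient designs, non-PSD covariances and
misaligned series raise errors. Cities with too few positive CEHWI days to
place exposure knots for a given type are skipped by the pipeline (logged),
since their first-stage model is not estimable.
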