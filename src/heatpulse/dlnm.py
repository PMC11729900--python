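"""First-stage city model: distributed-lag non-linear regression of daily
deaths on CEHWI.

The exposure enters through a *cross-basis*: the tensor product of a natural
cubic spline in the exposure dimension (default two internal knots at the
50th and 90th percentiles of the city's positive-CEHWI distribution) and a
natural cubic spline in the lag dimension over lags 0-6 days (3 df, internal
knots equally spaced on the log-lag scale).  The cross-basis joins a smooth
day-of-season term (ns, 4 df), relative humidity (ns, 3 df), year indicators
and day-of-week indicators in a log-linear model for the daily death count,
fitted by IRLS with the quasi-Poisson variance phi * mu (phi estimated from
the Pearson statistic).

The fitted cross-basis block is then *reduced* to the overall cumulative
association: summing the lag basis over lags 0-6 collapses the coefficient
matrix to a single exposure-dimension coefficient vector eta with covariance
S — the unit pooled across cities in the second stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .splines import SplineSpec, natural_cubic_basis, equal_quantile_spec

MAX_LAG = 6


def log_spaced_lag_knots(max_lag: int = MAX_LAG, n_knots: int = 1) -> tuple:
    """Internal lag knots equally spaced on the log scale of 1..max_lag."""
    pts = np.exp(np.linspace(np.log(1.0), np.log(float(max_lag)), n_knots + 2))
    return tuple(float(p) for p in pts[1:-1])


def default_lag_spec(max_lag: int = MAX_LAG, df: int = 3) -> SplineSpec:
    """Lag-dimension spline: natural cubic with intercept, ``df`` columns on
    lags 0..max_lag.  The intercept keeps effects that are constant across
    lags inside the model span, the usual cross-basis convention; the
    remaining knots sit at equally spaced log-lag positions."""
    n_internal = df - 2  # intercept + (n_internal + 1) spline columns
    if n_internal < 0:
        raise ValueError("lag df must be >= 2")
    return SplineSpec(internal_knots=log_spaced_lag_knots(max_lag, n_internal),
                      boundary_knots=(0.0, float(max_lag)), intercept=True)


def var_spec_from_exposure(cehwi, percentiles=(50.0, 90.0),
                           boundary: tuple | None = None,
                           boundary_percentile: float = 99.0) -> SplineSpec:
    """Exposure-dimension spline spec with internal knots at percentiles of
    the strictly positive CEHWI values (knots from all days would both sit at
    zero).  The upper boundary knot sits at the ``boundary_percentile`` of
    the positive values rather than the sample maximum, so the cubic region
    is supported by data and the few most extreme days are handled by the
    natural linear extrapolation."""
    x = np.asarray(cehwi, dtype=float)
    pos = x[x > 0]
    if pos.size < 10:
        raise ValueError(
            f"too few positive CEHWI values ({pos.size}) to place knots")
    knots = tuple(float(np.quantile(pos, p / 100.0)) for p in percentiles)
    if boundary is None:
        hi = float(np.quantile(pos, boundary_percentile / 100.0))
        if hi <= knots[-1]:
            hi = float(pos.max())
        boundary = (0.0, hi)
    if len(set(knots)) != len(knots):
        raise ValueError("tied exposure knots; distribution too discrete")
    return SplineSpec(internal_knots=knots, boundary_knots=boundary)


@dataclass
class CrossBasis:
    """Tensor-product design matrix of exposure and lag spline bases.

    ``matrix`` has one row per analysis day and ``v * ell`` columns ordered
    exposure-major: column (j, k) holds sum_l R_j(x_{g-l}) C_k(l).
    """

    matrix: np.ndarray
    days: pd.DatetimeIndex
    var_spec: SplineSpec | None  # None => linear (binary/identity) exposure
    lag_spec: SplineSpec
    max_lag: int = MAX_LAG

    @property
    def v(self) -> int:
        return 1 if self.var_spec is None else self.var_spec.dim

    @property
    def ell(self) -> int:
        return self.lag_spec.dim

    def var_basis(self, x) -> np.ndarray:
        if self.var_spec is None:
            return np.atleast_1d(np.asarray(x, dtype=float))[:, None]
        return np.atleast_2d(natural_cubic_basis(np.atleast_1d(x), self.var_spec))

    def lag_basis(self) -> np.ndarray:
        lags = np.arange(self.max_lag + 1, dtype=float)
        return natural_cubic_basis(lags, self.lag_spec)


def build_cross_basis(exposure: pd.Series, analysis_days: pd.DatetimeIndex,
                      var_spec: SplineSpec | None, lag_spec: SplineSpec | None = None,
                      max_lag: int = MAX_LAG) -> CrossBasis:
    """Cross-basis rows for ``analysis_days`` from a (longer, year-round)
    exposure series; every analysis day needs its ``max_lag`` preceding days
    defined in ``exposure``."""
    if lag_spec is None:
        lag_spec = default_lag_spec(max_lag)
    exposure = exposure.sort_index()
    pos = exposure.index.get_indexer(analysis_days)
    if np.any(pos < 0) or np.any(pos < max_lag):
        raise ValueError("analysis day without a defined lag-0..%d exposure history"
                         % max_lag)
    x = exposure.to_numpy(dtype=float)
    lagged = np.stack([x[pos - l] for l in range(max_lag + 1)], axis=1)  # (n, L+1)

    cb = CrossBasis(matrix=np.empty(0), days=analysis_days, var_spec=var_spec,
                    lag_spec=lag_spec, max_lag=max_lag)
    R = cb.var_basis(lagged.ravel()).reshape(len(analysis_days), max_lag + 1, cb.v)
    C = cb.lag_basis()  # (L+1, ell)
    M = np.einsum("glv,lk->gvk", R, C).reshape(len(analysis_days), cb.v * cb.ell)
    cb.matrix = M
    return cb


def covariate_matrix(days: pd.DatetimeIndex, humidity: pd.Series | None = None,
                     humidity_df: int = 3, season_df: int = 4,
                     pollutants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Confounder design: day-of-season ns(4), optional humidity ns(3),
    year and day-of-week indicators (reference levels dropped), optional
    same-day pollutant columns entered linearly."""
    cols = {}
    season_day = (days.dayofyear - pd.DatetimeIndex(
        [pd.Timestamp(y, 6, 1) for y in days.year]).dayofyear + 1).to_numpy()
    spec = equal_quantile_spec(np.arange(1, 93), df=season_df)
    B = natural_cubic_basis(season_day.astype(float), spec)
    for j in range(B.shape[1]):
        cols[f"season_ns{j+1}"] = B[:, j]
    if humidity is not None:
        rh = humidity.reindex(days)
        if rh.isna().any():
            raise ValueError("humidity missing for some analysis days")
        spec_rh = equal_quantile_spec(rh.to_numpy(), df=humidity_df)
        Brh = natural_cubic_basis(rh.to_numpy(dtype=float), spec_rh)
        for j in range(Brh.shape[1]):
            cols[f"rh_ns{j+1}"] = Brh[:, j]
    years = days.year.to_numpy()
    for y in np.unique(years)[1:]:
        cols[f"year_{y}"] = (years == y).astype(float)
    dows = days.dayofweek.to_numpy()
    for d in range(1, 7):
        cols[f"dow_{d}"] = (dows == d).astype(float)
    if pollutants is not None:
        for name in pollutants.columns:
            col = pollutants[name].reindex(days)
            if col.isna().any():
                raise ValueError(f"pollutant {name!r} missing for some days")
            cols[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=days)


@dataclass
class FirstStageFit:
    params: np.ndarray
    cov_params: np.ndarray
    beta: np.ndarray        # cross-basis block
    vcov_beta: np.ndarray
    dispersion: float
    cb: CrossBasis
    converged: bool
    colnames: list


def fit_first_stage(deaths: pd.Series, cb: CrossBasis,
                    covariates: pd.DataFrame | None = None) -> FirstStageFit:
    """Quasi-Poisson log-linear fit of daily deaths on the cross-basis plus
    confounders.  Dispersion phi-hat = Pearson chi^2 / (n - p); the reported
    coefficient covariance is phi-hat * (X'WX)^{-1}.
    """
    y = deaths.reindex(cb.days)
    if y.isna().any():
        raise ValueError("death counts missing for some analysis days")
    y = y.to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("death counts must be non-negative integers")
    if y.sum() == 0:
        raise ValueError("degenerate outcome: all death counts are zero")
    ncb = cb.matrix.shape[1]
    blocks = [np.ones((len(y), 1)), cb.matrix]
    names = ["intercept"] + [f"cb{j+1}" for j in range(ncb)]
    if covariates is not None and covariates.shape[1] > 0:
        blocks.append(covariates.to_numpy(dtype=float))
        names += list(covariates.columns)
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(scale="X2", maxiter=50, tol=1e-8)
    cov = np.asarray(res.cov_params())
    sl = slice(1, 1 + ncb)
    return FirstStageFit(
        params=np.asarray(res.params), cov_params=cov,
        beta=np.asarray(res.params)[sl], vcov_beta=cov[sl, sl],
        dispersion=float(res.scale), cb=cb,
        converged=bool(getattr(res, "converged", True)), colnames=names,
    )


@dataclass
class ReducedFit:
    """Overall cumulative association: eta (v-vector) with covariance S."""

    eta: np.ndarray
    S: np.ndarray
    var_spec: SplineSpec | None
    dispersion: float = 1.0

    def contrast(self, grid, reference: float = 0.0, cb_like: CrossBasis | None = None):
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        if self.var_spec is None:
            Z = grid[:, None] - float(reference)
        else:
            Z = (natural_cubic_basis(grid, self.var_spec)
                 - natural_cubic_basis(np.array([reference]), self.var_spec))
        return Z


def reduce_to_overall(fit: FirstStageFit) -> ReducedFit:
    """Collapse the cross-basis coefficients to the overall cumulative
    association: eta = (I_v kron u') beta with u the lag basis summed over
    lags 0..6, and S the congruent transform of the beta covariance."""
    cb = fit.cb
    u = cb.lag_basis().sum(axis=0)  # (ell,)
    M = np.kron(np.eye(cb.v), u[None, :])  # (v, v*ell)
    eta = M @ fit.beta
    S = M @ fit.vcov_beta @ M.T
    return ReducedFit(eta=eta, S=(S + S.T) / 2.0, var_spec=cb.var_spec,
                      dispersion=fit.dispersion)


def predict_overall_curve(red: ReducedFit, grid, reference: float = 0.0,
                          alpha: float = 0.05) -> pd.DataFrame:
    """RR(x) = exp((z(x) - z(ref))' eta) with delta-method CIs."""
    from scipy.stats import norm

    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    Z = red.contrast(grid, reference)
    logrr = Z @ red.eta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, red.S, Z), 0.0))
    zq = norm.ppf(1 - alpha / 2)
    return pd.DataFrame({
        "cehwi": grid, "logrr": logrr, "se": se,
        "rr": np.exp(logrr),
        "rr_low": np.exp(logrr - zq * se),
        "rr_high": np.exp(logrr + zq * se),
    })


def predict_lag_curve(fit: FirstStageFit, at: float, reference: float = 0.0,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Lag-specific RR at exposure ``at``: for each lag l,
    log-RR(l) = sum_{j,k} (R_j(at) - R_j(ref)) C_k(l) beta_{jk}."""
    from scipy.stats import norm

    cb = fit.cb
    r = (cb.var_basis(np.array([at])) - cb.var_basis(np.array([reference])))[0]
    C = cb.lag_basis()
    logrr = np.empty(cb.max_lag + 1)
    se = np.empty(cb.max_lag + 1)
    for l in range(cb.max_lag + 1):
        c = np.kron(r, C[l])
        logrr[l] = c @ fit.beta
        se[l] = np.sqrt(max(c @ fit.vcov_beta @ c, 0.0))
    zq = norm.ppf(1 - alpha / 2)
    return pd.DataFrame({
        "lag": np.arange(cb.max_lag + 1), "logrr": logrr, "se": se,
        "rr": np.exp(logrr),
        "rr_low": np.exp(logrr - zq * se),
        "rr_high": np.exp(logrr + zq * se),
    })
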