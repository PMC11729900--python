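import numpy as np
import pandas as pd
import pytest

from heatpulse import dlnm
from heatpulse.dlnm import (
    ReducedFit, build_cross_basis, default_lag_spec, fit_first_stage,
    predict_lag_curve, predict_overall_curve, reduce_to_overall,
    var_spec_from_exposure,
)
from heatpulse.splines import SplineSpec, natural_cubic_basis


def random_exposure(n=600, p=0.12, seed=0, start="2000-01-01"):
    rng = np.random.default_rng(seed)
    x = np.where(rng.random(n) < p, rng.gamma(2.0, 1.0, n), 0.0)
    return pd.Series(x, index=pd.date_range(start, periods=n, freq="D"))


@pytest.fixture(scope="module")
def cb_default():
    x = random_exposure()
    spec = var_spec_from_exposure(x.to_numpy())
    return build_cross_basis(x, x.index[7:], spec), x


class TestCrossBasis:
    def test_default_dimensions_are_three_by_three(self, cb_default):
        cb, _ = cb_default
        assert cb.v == 3 and cb.ell == 3
        assert cb.matrix.shape[1] == 9

    def test_constant_exposure_row_is_kronecker_identity(self):
        idx = pd.date_range("2000-01-01", periods=40, freq="D")
        x = pd.Series(1.3, index=idx)
        spec = SplineSpec((0.5, 1.5), (0.0, 3.0))
        cb = build_cross_basis(x, idx[10:], spec)
        R = natural_cubic_basis(np.array([1.3]), spec)[0]
        u = cb.lag_basis().sum(axis=0)
        expected = np.kron(R, u)
        assert np.allclose(cb.matrix[0], expected, atol=1e-12)

    def test_zero_history_row_matches_reference(self, cb_default):
        cb, x = cb_default
        lagged_zero = np.array([
            all(x.iloc[i - l + 7] == 0 for l in range(7))
            for i in range(len(cb.days))
        ])
        ref_row = np.kron(natural_cubic_basis(np.array([0.0]), cb.var_spec)[0],
                          cb.lag_basis().sum(axis=0))
        rows = cb.matrix[lagged_zero]
        assert len(rows) > 0
        assert np.allclose(rows, ref_row[None, :], atol=1e-12)

    def test_missing_history_rejected(self):
        x = random_exposure(30)
        with pytest.raises(ValueError):
            build_cross_basis(x, x.index[:10], var_spec_from_exposure(x.to_numpy()))

    def test_lag_spec_has_intercept_and_log_midpoint_knot(self):
        spec = default_lag_spec()
        assert spec.intercept and spec.dim == 3
        (k,) = spec.internal_knots
        assert np.isclose(k, np.sqrt(6.0))  # log-midpoint of 1..6


def simulate_poisson_city(beta, cb, seed, baseline=100.0):
    rng = np.random.default_rng(seed)
    mu = baseline * np.exp(cb.matrix @ beta)
    y = rng.poisson(mu)
    return pd.Series(y, index=cb.days)


class TestFirstStageFit:
    def test_recovers_known_coefficients(self):
        x = random_exposure(2000, seed=1)
        spec = var_spec_from_exposure(x.to_numpy())
        cb = build_cross_basis(x, x.index[7:], spec)
        rng = np.random.default_rng(2)
        beta = 0.02 * rng.standard_normal(9)
        hits = 0
        reps = 30
        for r in range(reps):
            y = simulate_poisson_city(beta, cb, seed=100 + r)
            fit = fit_first_stage(y, cb)
            se = np.sqrt(np.diag(fit.vcov_beta))
            hits += int(np.all(np.abs(fit.beta - beta) < 3 * se))
        assert hits >= int(0.9 * reps)

    def test_poisson_dispersion_near_one(self):
        x = random_exposure(20_000, seed=3)
        spec = var_spec_from_exposure(x.to_numpy())
        cb = build_cross_basis(x, x.index[7:], spec)
        y = simulate_poisson_city(np.zeros(9), cb, seed=4)
        fit = fit_first_stage(y, cb)
        assert abs(fit.dispersion - 1.0) < 0.1

    def test_all_zero_deaths_rejected(self, cb_default):
        cb, _ = cb_default
        y = pd.Series(0, index=cb.days)
        with pytest.raises(ValueError):
            fit_first_stage(y, cb)

    def test_covariance_is_symmetric_psd(self, cb_default):
        cb, _ = cb_default
        y = simulate_poisson_city(np.zeros(9), cb, seed=5)
        fit = fit_first_stage(y, cb)
        assert np.allclose(fit.vcov_beta, fit.vcov_beta.T)
        assert np.linalg.eigvalsh(fit.vcov_beta).min() > -1e-10


class TestReduction:
    def test_zero_coefficients_give_flat_curve(self, cb_default):
        cb, _ = cb_default
        y = simulate_poisson_city(np.zeros(9), cb, seed=6)
        fit = fit_first_stage(y, cb)
        fit.beta = np.zeros(9)
        red = reduce_to_overall(fit)
        assert np.allclose(red.eta, 0.0)
        curve = predict_overall_curve(red, [0.0, 1.0, 2.0])
        assert np.allclose(curve["rr"], 1.0)

    def test_overall_equals_sum_of_lag_specific(self, cb_default):
        cb, _ = cb_default
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = simulate_poisson_city(0.03 * rng.standard_normal(9), cb,
                                      seed=rng.integers(1 << 30))
            fit = fit_first_stage(y, cb)
            red = reduce_to_overall(fit)
            for at in (0.5, 1.5, 2.5):
                overall = predict_overall_curve(red, [at])["logrr"].iloc[0]
                lag = predict_lag_curve(fit, at)["logrr"].sum()
                assert overall == pytest.approx(lag, abs=1e-10)

    def test_reduced_covariance_inherits_psd(self, cb_default):
        cb, _ = cb_default
        y = simulate_poisson_city(np.zeros(9), cb, seed=8)
        red = reduce_to_overall(fit_first_stage(y, cb))
        assert np.allclose(red.S, red.S.T)
        assert np.linalg.eigvalsh(red.S).min() > -1e-12


class TestPrediction:
    def test_reference_rr_is_one_with_zero_width(self, cb_default):
        cb, _ = cb_default
        y = simulate_poisson_city(np.full(9, 0.01), cb, seed=9)
        red = reduce_to_overall(fit_first_stage(y, cb))
        row = predict_overall_curve(red, [0.0]).iloc[0]
        assert row["rr"] == pytest.approx(1.0)
        assert row["se"] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_linear_log_rr_truth(self):
        # truth: overall cumulative log-RR(x) = 0.02 x, spread evenly on lags
        x = random_exposure(8000, p=0.3, seed=10)
        spec = var_spec_from_exposure(x.to_numpy())
        cb = build_cross_basis(x, x.index[7:], spec)
        pos = x.index.get_indexer(cb.days)
        xv = x.to_numpy()
        lagged = np.stack([xv[pos - l] for l in range(7)], axis=1)
        mu = 200.0 * np.exp(0.02 * lagged.mean(axis=1))
        y = pd.Series(np.random.default_rng(11).poisson(mu), index=cb.days)
        red = reduce_to_overall(fit_first_stage(y, cb))
        grid = np.linspace(0.5, spec.boundary_knots[1] * 0.9, 8)
        curve = predict_overall_curve(red, grid)
        assert np.allclose(curve["logrr"], 0.02 * grid, atol=0.01)

    def test_lag_curve_flat_at_reference_exposure(self, cb_default):
        cb, _ = cb_default
        y = simulate_poisson_city(np.full(9, 0.02), cb, seed=12)
        fit = fit_first_stage(y, cb)
        lagc = predict_lag_curve(fit, at=0.0)
        assert np.allclose(lagc["rr"], 1.0)

    def test_ci_width_grows_away_from_reference(self, cb_default):
        cb, _ = cb_default
        y = simulate_poisson_city(np.zeros(9), cb, seed=13)
        red = reduce_to_overall(fit_first_stage(y, cb))
        grid = np.linspace(0.0, 2.0, 9)
        se = predict_overall_curve(red, grid)["se"].to_numpy()
        # empirical tendency, not a theorem: small boundary dips tolerated
        assert se[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(se) >= -0.05 * se.max())
        assert se[-1] > se[1]


def test_covariate_matrix_shapes_and_rank():
    days = pd.DatetimeIndex([d for y in (2000, 2001)
                             for d in pd.date_range(f"{y}-06-01", f"{y}-08-31")])
    rh = pd.Series(np.random.default_rng(0).uniform(40, 90, len(days)), index=days)
    X = dlnm.covariate_matrix(days, humidity=rh)
    # season ns(4) + rh ns(3) + 1 year indicator + 6 dow indicators
    assert X.shape == (len(days), 4 + 3 + 1 + 6)
    full = np.column_stack([np.ones(len(days)), X.to_numpy()])
    assert np.linalg.matrix_rank(full) == full.shape[1]
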