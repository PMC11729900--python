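import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatpulse import exposure
from heatpulse.exposure import (
    DayPartition, calendar_thresholds, classify_heatwaves, compute_cehwi,
    daily_summaries, solar_day_partition,
)

from conftest import (
    brute_force_classify, constant_thresholds, daily_from_flags, make_hourly,
)


class TestDailySummaries:
    def test_constant_day(self):
        out = daily_summaries(make_hourly([20.0]))
        assert (out.iloc[0][["tmax", "tmin", "tmean"]] == 20.0).all()

    def test_direct_arithmetic(self):
        out = daily_summaries(make_hourly([np.arange(1.0, 25.0)]))
        row = out.iloc[0]
        assert (row["tmax"], row["tmin"], row["tmean"]) == (24.0, 1.0, 12.5)

    def test_incomplete_day_flagged_and_excludable(self):
        hourly = make_hourly([20.0, 21.0]).iloc[:-1]  # second day has 23 h
        out = daily_summaries(hourly)
        assert out["complete"].tolist() == [True, False]
        assert len(daily_summaries(hourly, require_complete=True)) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            daily_summaries(pd.Series([], dtype=float, index=pd.DatetimeIndex([])))


class TestCalendarThresholds:
    @staticmethod
    def _daily(values_by_date):
        dates = pd.DatetimeIndex(sorted(values_by_date))
        v = np.array([values_by_date[d] for d in dates])
        return pd.DataFrame({"tmax": v, "tmin": v - 5, "tmean": v - 2.5,
                             "n_hours": 24, "complete": True}, index=dates)

    def test_constant_pool_returns_constant(self):
        dates = pd.date_range("2000-01-01", "2001-12-31", freq="D")
        daily = self._daily({d: 25.0 for d in dates})
        thr = calendar_thresholds(daily)
        assert np.allclose(thr["tmax"], 25.0)

    def test_type7_quantile_of_window_pool(self):
        # window pool for July 15 holds exactly the values 1..30 over 2 years
        dates = pd.date_range("2000-01-01", "2001-12-31", freq="D")
        vals = {d: 0.0 for d in dates}
        window = pd.date_range("2000-07-08", "2000-07-22", freq="D")
        for i, d in enumerate(window):
            vals[d] = float(i + 1)
            vals[d + pd.offsets.DateOffset(years=1)] = float(i + 16)
        thr = calendar_thresholds(self._daily(vals))
        slot = exposure.calendar_slot(pd.DatetimeIndex(["2000-07-15"]))[0]
        # h = (n-1)p + 1 = 27.1 for n=30, p=0.9 under linear interpolation
        assert thr["tmax"].iloc[slot] == pytest.approx(27.1, abs=1e-12)

    def test_alternative_percentiles_accepted(self):
        dates = pd.date_range("2000-01-01", "2001-12-31", freq="D")
        daily = self._daily({d: float(hash(d) % 100) for d in dates})
        for p in (92.5, 95.0, 97.5):
            thr = calendar_thresholds(daily, percentile=p)
            assert thr.attrs["percentile"] == p

    @pytest.mark.parametrize("kwargs", [
        {"window": 14}, {"window": 0}, {"percentile": 0.0}, {"percentile": 100.0},
    ])
    def test_invalid_options_rejected(self, kwargs):
        dates = pd.date_range("2000-01-01", "2001-12-31", freq="D")
        daily = self._daily({d: 1.0 for d in dates})
        with pytest.raises(ValueError):
            calendar_thresholds(daily, **kwargs)

    def test_single_year_rejected(self):
        dates = pd.date_range("2000-01-01", "2000-12-31", freq="D")
        with pytest.raises(ValueError):
            calendar_thresholds(self._daily({d: 1.0 for d in dates}))


class TestClassifyHeatwaves:
    thr = constant_thresholds()

    def run(self, hmax, hmin, min_duration=2):
        daily = daily_from_flags(hmax, hmin, self.thr)
        return classify_heatwaves(daily, self.thr, min_duration=min_duration)

    def test_three_hot_days_one_dhw_event(self):
        cal = self.run([1, 1, 1, 0], [0, 0, 0, 0])
        assert cal["type"].tolist() == ["dhw", "dhw", "dhw", "none"]
        assert cal["event_id"].tolist() == [0, 0, 0, -1]

    def test_isolated_compound_day_below_duration(self):
        cal = self.run([0, 1, 0], [0, 1, 0])
        assert (cal["type"] == "none").all()

    def test_two_compound_days_one_chw_event(self):
        cal = self.run([0, 0, 0, 1, 1], [0, 0, 0, 1, 1])
        assert cal["type"].tolist() == ["none"] * 3 + ["chw", "chw"]
        assert cal.loc[cal["type"] == "chw", "event_id"].nunique() == 1

    def test_runs_split_at_type_changes(self):
        # two hot-day-only days then two compound days: separate events
        cal = self.run([1, 1, 1, 1], [0, 0, 1, 1])
        assert cal["type"].tolist() == ["dhw", "dhw", "chw", "chw"]
        assert cal["event_id"].nunique() == 2

    @settings(max_examples=150, deadline=None)
    @given(
        flags=st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                       max_size=40),
        min_dur=st.integers(1, 4),
    )
    def test_agrees_with_brute_force_scan(self, flags, min_dur):
        hmax = [f[0] for f in flags]
        hmin = [f[1] for f in flags]
        cal = self.run(hmax, hmin, min_duration=min_dur)
        assert cal["type"].tolist() == brute_force_classify(hmax, hmin, min_dur)


class TestComputeCEHWI:
    thr = constant_thresholds(tmax=25.0, tmin=20.0, tmean=22.5)

    def test_mean_daytime_exceedance(self):
        # daytime hours at threshold except three exceeding by 1, 2, 3 deg
        day = np.full(24, 15.0)
        day[6:18] = 25.0  # at threshold: not exceeding (strict >)
        day[8], day[9], day[10] = 26.0, 27.0, 28.0
        hourly = make_hourly([day, day])
        daily = daily_summaries(hourly)
        cal = pd.DataFrame({"type": ["dhw", "dhw"], "event_id": [0, 0]},
                           index=daily.index)
        out = compute_cehwi(hourly, self.thr, cal)
        assert out["cehwi_dhw"].iloc[0] == pytest.approx(2.0)
        assert (out["cehwi_nhw"] == 0).all() and (out["cehwi_chw"] == 0).all()

    def test_no_exceeding_hour_gives_zero(self):
        hourly = make_hourly([15.0, 15.0])
        daily = daily_summaries(hourly)
        cal = pd.DataFrame({"type": ["dhw", "dhw"], "event_id": [0, 0]},
                           index=daily.index)
        out = compute_cehwi(hourly, self.thr, cal)
        assert (out == 0).all().all()

    def test_constant_exceedance_on_compound_day(self):
        hourly = make_hourly([23.0, 23.0])  # 0.5 above the tmean threshold
        daily = daily_summaries(hourly)
        cal = pd.DataFrame({"type": ["chw", "chw"], "event_id": [0, 0]},
                           index=daily.index)
        out = compute_cehwi(hourly, self.thr, cal)
        assert np.allclose(out["cehwi_chw"], 0.5)

    def test_nighttime_and_evening_hours_pooled_for_nhw(self):
        day = np.full(24, 15.0)
        day[2] = 21.0   # nighttime, +1
        day[20] = 23.0  # evening, +3
        day[10] = 30.0  # daytime, must not count for NHW
        hourly = make_hourly([day, day])
        daily = daily_summaries(hourly)
        cal = pd.DataFrame({"type": ["nhw", "nhw"], "event_id": [0, 0]},
                           index=daily.index)
        out = compute_cehwi(hourly, self.thr, cal)
        assert out["cehwi_nhw"].iloc[0] == pytest.approx(2.0)

    def test_positive_only_inside_events(self, small_city):
        c = small_city
        for t in ("dhw", "nhw", "chw"):
            pos = c["cehwi"][f"cehwi_{t}"] > 0
            assert (c["cal"].loc[pos, "type"] == t).all()

    def test_types_mutually_exclusive(self, small_city):
        pos = (small_city["cehwi"] > 0).sum(axis=1)
        assert pos.max() <= 1


class TestProperties:
    def test_raising_percentile_never_adds_event_days(self, small_city):
        daily = small_city["daily"]
        counts = []
        for p in (90.0, 95.0):
            thr = calendar_thresholds(daily, percentile=p)
            cal = classify_heatwaves(daily, thr)
            counts.append(int((cal["type"] != "none").sum()))
        assert counts[1] <= counts[0]

    def test_threshold_exceedance_near_nominal_rate(self, small_city):
        flags = exposure.exceedance_flags(small_city["daily"], small_city["thr"])
        rate = flags["hmax"].mean()
        assert abs(rate - 0.10) < 0.02


def test_solar_partition_sane_at_midlatitude():
    dates = pd.DatetimeIndex(["2001-03-21", "2001-06-21", "2001-12-21"])
    part = solar_day_partition(35.0, 135.0, dates, utc_offset=9.0)
    assert (part["sunrise"] < part["sunset"]).all()
    # equinox sunrise near 06:00 local; summer day longer than winter day
    assert abs(part["sunrise"].iloc[0] - 6.0) < 0.75
    daylen = part["sunset"] - part["sunrise"]
    assert daylen.iloc[1] > daylen.iloc[2]


def test_gap_in_hourly_series_rejected():
    hourly = make_hourly([20.0, 21.0])
    broken = hourly.drop(hourly.index[30])
    with pytest.raises(ValueError):
        exposure.validate_hourly(broken)
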