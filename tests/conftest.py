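import numpy as np
import pandas as pd
import pytest

from heatpulse import exposure


def make_hourly(daily_values):
    """Hourly series from a list of per-day 24-value arrays (or scalars)."""
    days = []
    for v in daily_values:
        v = np.asarray(v, dtype=float)
        days.append(np.full(24, v) if v.ndim == 0 else v)
    idx = pd.date_range("2001-06-01", periods=24 * len(days), freq="h")
    return pd.Series(np.concatenate(days), index=idx, name="temp_c")


def constant_thresholds(tmax=25.0, tmin=20.0, tmean=22.5):
    thr = pd.DataFrame(
        {"tmax": tmax, "tmin": tmin, "tmean": tmean},
        index=pd.RangeIndex(365, name="slot"),
    )
    thr.attrs.update(percentile=90.0, window=15, reference_years=[2000, 2001])
    return thr


def daily_from_flags(hmax, hmin, thr):
    """Daily summaries realising given hot-day/hot-night flag patterns."""
    n = len(hmax)
    dates = pd.date_range("2001-06-01", periods=n, freq="D")
    tmax = np.where(hmax, thr["tmax"].iloc[0] + 1.0, thr["tmax"].iloc[0] - 1.0)
    tmin = np.where(hmin, thr["tmin"].iloc[0] + 1.0, thr["tmin"].iloc[0] - 1.0)
    return pd.DataFrame(
        {"tmax": tmax, "tmin": tmin, "tmean": (tmax + tmin) / 2,
         "n_hours": 24, "complete": True},
        index=dates,
    )


def brute_force_classify(hmax, hmin, min_duration):
    """Independent heatwave labelling: candidate type per day from the joint
    flags, then every maximal run of one candidate type over consecutive days
    is checked against the duration rule by scanning all subsequences."""
    n = len(hmax)
    cand = []
    for i in range(n):
        if hmax[i] and hmin[i]:
            cand.append("chw")
        elif hmax[i]:
            cand.append("dhw")
        elif hmin[i]:
            cand.append("nhw")
        else:
            cand.append("none")
    labels = ["none"] * n
    for i in range(n):
        for j in range(i + min_duration - 1, n):
            window = cand[i:j + 1]
            if window[0] == "none" or any(c != window[0] for c in window):
                break
            for g in range(i, j + 1):
                labels[g] = window[0]
    return labels


@pytest.fixture(scope="session")
def small_city():
    """One synthetic city with 10 years of hourly data and its exposure chain,
    shared across tests that only read it."""
    from heatpulse import pipeline, synth

    climate = synth.ClimateScenario(years=10, seed=11)
    hourly = synth.generate_hourly_temperature(climate)
    (daily, thr), cal, cehwi = pipeline.exposure_chain(hourly)
    return {"climate": climate, "hourly": hourly, "daily": daily,
            "thr": thr, "cal": cal, "cehwi": cehwi}
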