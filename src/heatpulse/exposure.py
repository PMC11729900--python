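"""Heatwave detection and the Cumulative Excess Heatwave Index (CEHWI).

Three heatwave types are distinguished from daily summaries of hourly
temperature:

* **DHW** (daytime-only): runs of at least ``min_duration`` consecutive days
  on which Tmax reaches its calendar-day threshold while Tmin stays below its
  own threshold — hot days without hot nights.
* **NHW** (nighttime-only): the mirror case, hot nights without hot days.
* **CHW** (compound): runs on which both Tmax and Tmin exceed their
  thresholds.

Thresholds are calendar-day percentiles (default the 90th) of the long-term
distribution pooled over a sliding window (default 15 days) centred on each
calendar day, so early- and late-summer events are detected against their own
local climatology rather than a seasonal constant.

For each day ``g`` of a type-``i`` event the CEHWI is the mean hourly
exceedance over exceeding hours within the type's diel period:

    CEHWI_ig = sum_j (t_jg - Thr_ig) * 1[t_jg > Thr_ig] / n_ig

where the hours ``j`` range over the daytime (DHW), nighttime plus evening
(NHW) or the whole day (CHW); ``Thr_ig`` is the calendar-day threshold of
Tmax, Tmin or Tmean respectively; and ``n_ig`` counts the exceeding hours.
Days with no exceeding hour, and days outside events, carry CEHWI = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HW_TYPES = ("dhw", "nhw", "chw")
_METRIC_FOR_TYPE = {"dhw": "tmax", "nhw": "tmin", "chw": "tmean"}

# cumulative days before each month in a 365-day (non-leap) year
_CUM_DAYS = np.concatenate([[0], np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30])])


def calendar_slot(index: pd.DatetimeIndex) -> np.ndarray:
    """Map dates to a 0..364 calendar slot; Feb 29 shares Feb 28's slot."""
    month = index.month.to_numpy()
    day = index.day.to_numpy()
    day = np.where((month == 2) & (day == 29), 28, day)
    return _CUM_DAYS[month - 1] + day - 1


@dataclass(frozen=True)
class DayPartition:
    """Diel partition of the 24 hours into nighttime, daytime and evening.

    ``sunrise`` and ``sunset`` are fractional local hours; hour-of-day ``h``
    (the label of the hourly sample covering ``[h, h+1)``) is daytime when
    ``sunrise <= h < sunset``, nighttime when ``h < sunrise`` and evening when
    ``h >= sunset``.  A single fixed pair covers the synthetic default; pass a
    per-day frame from :func:`solar_day_partition` for location-aware times.
    """

    sunrise: float = 6.0
    sunset: float = 18.0

    def __post_init__(self):
        if not 0.0 < self.sunrise < self.sunset < 24.0:
            raise ValueError(
                f"need 0 < sunrise < sunset < 24, got ({self.sunrise}, {self.sunset})"
            )

    def daytime_mask(self, hours: np.ndarray) -> np.ndarray:
        return (hours >= self.sunrise) & (hours < self.sunset)


def solar_day_partition(latitude: float, longitude: float, dates: pd.DatetimeIndex,
                        utc_offset: float | None = None) -> pd.DataFrame:
    """Sunrise/sunset local clock times from the NOAA solar position equations.

    Returns a frame indexed by date with fractional-hour ``sunrise`` and
    ``sunset`` columns.  ``utc_offset`` defaults to the nominal zone
    ``round(longitude / 15)``.  Polar day/night clamps to (0.01, 23.99).
    """
    if utc_offset is None:
        utc_offset = round(longitude / 15.0)
    doy = dates.dayofyear.to_numpy()
    # fractional year at solar noon, radians
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + 0.5)
    eqtime = 229.18 * (
        0.000075 + 0.001868 * np.cos(gamma) - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma) - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma)
    )
    lat = np.deg2rad(latitude)
    cos_ha = (
        np.cos(np.deg2rad(90.833)) / (np.cos(lat) * np.cos(decl))
        - np.tan(lat) * np.tan(decl)
    )
    cos_ha = np.clip(cos_ha, -1.0, 1.0)
    ha = np.rad2deg(np.arccos(cos_ha))
    sunrise_utc_min = 720.0 - 4.0 * (longitude + ha) - eqtime
    sunset_utc_min = 720.0 - 4.0 * (longitude - ha) - eqtime
    sunrise = np.clip(sunrise_utc_min / 60.0 + utc_offset, 0.01, 23.98)
    sunset = np.clip(sunset_utc_min / 60.0 + utc_offset, 0.02, 23.99)
    return pd.DataFrame({"sunrise": sunrise, "sunset": sunset}, index=dates.normalize())


def validate_hourly(series: pd.Series) -> pd.Series:
    """Check an hourly temperature series: datetime index, strictly increasing
    at one-hour spacing, finite values.  Gaps raise rather than being filled."""
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("hourly series must have a DatetimeIndex")
    if len(series) == 0:
        raise ValueError("empty hourly series")
    deltas = np.diff(series.index.asi8)
    if len(deltas) and not np.all(deltas == 3_600_000_000_000):
        raise ValueError("timestamps must be strictly increasing at 1-hour spacing")
    if not np.all(np.isfinite(series.to_numpy(dtype=float))):
        raise ValueError("non-finite temperature values")
    return series


def daily_summaries(series: pd.Series, require_complete: bool = False) -> pd.DataFrame:
    """Daily Tmax/Tmin/Tmean from hourly temperature.

    Returns a frame indexed by (normalized) date with columns ``tmax``,
    ``tmin``, ``tmean``, ``n_hours`` and ``complete``.  Days with fewer than
    24 hourly values are flagged incomplete; they are excluded from threshold
    estimation downstream but kept here so event days with partial data remain
    visible.
    """
    if len(series) == 0:
        raise ValueError("empty hourly series")
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("hourly series must have a DatetimeIndex")
    grp = series.groupby(series.index.normalize())
    out = grp.agg(tmax="max", tmin="min", tmean="mean", n_hours="size")
    out["complete"] = out["n_hours"] == 24
    if require_complete:
        out = out[out["complete"]]
    out.index.name = "date"
    return out


def calendar_thresholds(daily: pd.DataFrame, percentile: float = 90.0,
                        window: int = 15) -> pd.DataFrame:
    """Calendar-day percentile thresholds for Tmax/Tmin/Tmean.

    The threshold for calendar day ``d`` and metric ``m`` is the
    ``percentile``-th sample quantile (linear interpolation, the "type 7"
    convention) of all complete-day values of ``m`` whose calendar day falls
    within the ``window``-day window centred on ``d``, pooled across all
    reference years.  The window wraps across the year boundary.

    Returns a frame indexed by calendar slot 0..364 with columns ``tmax``,
    ``tmin``, ``tmean`` and metadata in ``.attrs``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    use = daily[daily["complete"]] if "complete" in daily else daily
    years = use.index.year.unique()
    if len(years) < 2:
        raise ValueError("need at least 2 years of daily summaries for thresholds")
    slots = calendar_slot(use.index)
    half = window // 2
    # per-slot value arrays, then pool each slot's +-half neighbourhood
    vals = {m: use[m].to_numpy(dtype=float) for m in ("tmax", "tmin", "tmean")}
    order = np.argsort(slots, kind="stable")
    sorted_slots = slots[order]
    bounds = np.searchsorted(sorted_slots, np.arange(366))
    out = {m: np.empty(365) for m in vals}
    for d in range(365):
        wanted = (np.arange(d - half, d + half + 1)) % 365
        idx = np.concatenate([order[bounds[w]:bounds[w + 1]] for w in wanted])
        if idx.size == 0:
            raise ValueError(f"no data in window around calendar slot {d}")
        for m in vals:
            out[m][d] = np.quantile(vals[m][idx], percentile / 100.0)
    thr = pd.DataFrame(out, index=pd.RangeIndex(365, name="slot"))
    thr.attrs.update(percentile=percentile, window=window,
                     reference_years=[int(y) for y in years])
    return thr


def exceedance_flags(daily: pd.DataFrame, thr: pd.DataFrame) -> pd.DataFrame:
    """Per-day hot-day (Tmax) and hot-night (Tmin) flags against the calendar
    thresholds."""
    slots = calendar_slot(daily.index)
    missing = set(np.unique(slots)) - set(thr.index)
    if missing:
        raise ValueError(f"thresholds missing for calendar slots {sorted(missing)}")
    hmax = daily["tmax"].to_numpy() >= thr["tmax"].to_numpy()[slots]
    hmin = daily["tmin"].to_numpy() >= thr["tmin"].to_numpy()[slots]
    return pd.DataFrame({"hmax": hmax, "hmin": hmin}, index=daily.index)


def classify_heatwaves(daily: pd.DataFrame, thr: pd.DataFrame,
                       min_duration: int = 2) -> pd.DataFrame:
    """Label each day none/DHW/NHW/CHW and group consecutive same-type days.

    A day is a candidate DHW day when Tmax >= threshold and Tmin < threshold,
    NHW when only Tmin exceeds, CHW when both do.  Maximal runs of
    ``min_duration`` or more consecutive calendar days of the same candidate
    type become events (runs are split where the type changes); shorter runs
    are dropped.  Returns a frame indexed by date with ``type`` in
    {"none","dhw","nhw","chw"} and integer ``event_id`` (-1 off events).
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    flags = exceedance_flags(daily, thr)
    cand = np.where(
        flags["hmax"] & flags["hmin"], "chw",
        np.where(flags["hmax"], "dhw", np.where(flags["hmin"], "nhw", "none")),
    )
    dates = daily.index
    day_gap = np.diff(dates.asi8) // 86_400_000_000_000
    out_type = np.full(len(dates), "none", dtype=object)
    event_id = np.full(len(dates), -1, dtype=int)
    next_id = 0
    start = 0
    for i in range(1, len(dates) + 1):
        boundary = (
            i == len(dates)
            or cand[i] != cand[start]
            or day_gap[i - 1] != 1
        )
        if boundary:
            if cand[start] != "none" and i - start >= min_duration:
                out_type[start:i] = cand[start]
                event_id[start:i] = next_id
                next_id += 1
            start = i
    return pd.DataFrame({"type": out_type, "event_id": event_id}, index=dates)


def compute_cehwi(series: pd.Series, thr: pd.DataFrame, cal: pd.DataFrame,
                  part: DayPartition | pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-day CEHWI for each heatwave type.

    Returns a frame indexed by date with ``cehwi_dhw``, ``cehwi_nhw`` and
    ``cehwi_chw``; a value is positive only on days labelled with that type in
    ``cal``, and is the mean exceedance of hourly temperature over the
    calendar-day threshold across exceeding hours of the type's diel period
    (daytime for DHW, nighttime plus evening for NHW, all 24 h for CHW).
    """
    if part is None:
        part = DayPartition()
    dates = series.index.normalize()
    hours = series.index.hour.to_numpy() + series.index.minute.to_numpy() / 60.0
    if isinstance(part, pd.DataFrame):
        sunrise = part["sunrise"].reindex(dates).to_numpy()
        sunset = part["sunset"].reindex(dates).to_numpy()
        if np.any(~np.isfinite(sunrise)) or np.any(~np.isfinite(sunset)):
            raise ValueError("day partition does not cover all dates")
        day_mask = (hours >= sunrise) & (hours < sunset)
    else:
        day_mask = part.daytime_mask(hours)
    night_mask = ~day_mask

    temps = series.to_numpy(dtype=float)
    slots = calendar_slot(series.index)
    out = pd.DataFrame(0.0, index=cal.index, columns=[f"cehwi_{t}" for t in HW_TYPES])

    event_days = cal.index[cal["type"] != "none"]
    if len(event_days) == 0:
        return out
    day_of = pd.Series(np.arange(len(cal)), index=cal.index)
    # positions of each hourly sample's date within cal, -1 when absent
    pos = day_of.reindex(dates, fill_value=-1).to_numpy()

    types = cal["type"].to_numpy()
    for t, mask in (("dhw", day_mask), ("nhw", night_mask),
                    ("chw", np.ones_like(day_mask))):
        metric = _METRIC_FOR_TYPE[t]
        sel_days = np.flatnonzero(types == t)
        if sel_days.size == 0:
            continue
        in_type = np.isin(pos, sel_days) & mask
        if not in_type.any():
            raise ValueError(f"event day with no hourly data for type {t!r}")
        thr_vals = thr[metric].to_numpy()[slots[in_type]]
        excess = temps[in_type] - thr_vals
        exceeding = excess > 0
        sums = np.bincount(pos[in_type][exceeding], weights=excess[exceeding],
                           minlength=len(cal))
        counts = np.bincount(pos[in_type][exceeding], minlength=len(cal))
        # days in events present in cal but with zero hourly samples are errors
        covered = np.bincount(pos[in_type], minlength=len(cal)) > 0
        if not covered[sel_days].all():
            raise ValueError("event day with no hourly data")
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        out[f"cehwi_{t}"] = vals
    return out


def event_day_count(cal: pd.DataFrame, hw_type: str | None = None) -> int:
    if hw_type is None:
        return int((cal["type"] != "none").sum())
    return int((cal["type"] == hw_type).sum())
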