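"""Atmospheric heatwave detection and counterfactual DO impact.

A heatwave over a lake is a run of at least five consecutive days on
which daily air temperature exceeds a *day-specific* threshold: the 90th
percentile of that calendar day's temperatures over a fixed baseline
climatology (default 1970–1999).  Day-specific thresholds let winter
heatwaves be detected at lower absolute temperatures than summer ones.

Impacts on dissolved oxygen are quantified counterfactually with a
fitted DO model: each heatwave day is predicted twice, once with the
actual temperature and once with that calendar day's climatological mean
temperature (all other features unchanged).  The signed percent
difference, ``100*(DO_actual - DO_clim)/DO_clim``, is the *influence
intensity* (negative = deoxygenation).  The long-term impact compares
multi-year mean DO between the actual series and a scenario in which
every heatwave day's temperature is replaced by the climatological mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trend_analysis import theil_sen

__all__ = [
    "doy_365",
    "day_climatology",
    "detect_events",
    "duration_stats",
    "influence_intensity",
    "longterm_impact",
    "DayClimatology",
    "HeatwaveEvent",
    "InfluenceReport",
]

DEFAULT_PERCENTILE = 90.0
DEFAULT_MIN_DURATION = 5


def doy_365(dates) -> np.ndarray:
    """Map dates onto a fixed 1..365 day-of-year grid.

    Feb 29 shares slot 59 with Feb 28 (all later days of a leap year are
    shifted down by one), so climatology arrays have a fixed length.
    """
    idx = pd.DatetimeIndex(dates)
    doy = idx.dayofyear.to_numpy().astype(int)
    leap = idx.is_leap_year
    doy = np.where(leap & (doy >= 60), doy - 1, doy)
    return doy


@dataclass
class DayClimatology:
    """Per-calendar-day baseline mean and exceedance threshold (length 365)."""

    mean_temp: np.ndarray       # degC, baseline mean per day-of-year
    threshold: np.ndarray       # degC, baseline percentile per day-of-year
    percentile: float
    window_halfwidth: int
    n_years: int


@dataclass
class HeatwaveEvent:
    """A maximal exceedance run of at least the minimum duration."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration: int               # days, inclusive
    exceedance: float           # mean degC above the day-specific threshold
    lake_id: object = None


@dataclass
class InfluenceReport:
    """Counterfactual heatwave-impact summary for one lake."""

    mean_intensity: float             # percent, day-weighted mean
    max_intensity: float              # percent, largest |value|, sign kept
    event_intensities: list = field(default_factory=list)
    n_heatwave_days: int = 0
    longterm_mean_impact: float = float("nan")   # percent
    do_rate_actual: float = float("nan")         # mg/L per decade
    do_rate_no_hw: float = float("nan")          # mg/L per decade


def day_climatology(
    dates,
    temps,
    *,
    percentile: float = DEFAULT_PERCENTILE,
    window_halfwidth: int = 0,
) -> DayClimatology:
    """Baseline per-day mean and percentile threshold.

    Pools, for each of the 365 calendar-day slots, all baseline values
    within ``window_halfwidth`` days of that slot (default 0 = strict
    calendar-day pooling) and takes the mean and the linear-interpolation
    percentile.  Warns below 10 baseline years; errors below 2.
    """
    t = np.asarray(temps, dtype=float)
    doy = doy_365(dates)
    n_years = len(np.unique(pd.DatetimeIndex(dates).year))
    if n_years < 2:
        raise ValueError("baseline must span at least 2 years")
    if n_years < 10:
        import warnings

        warnings.warn(f"baseline spans only {n_years} years; climatology is noisy")

    by_day = [t[doy == d] for d in range(1, 366)]
    mean = np.empty(365)
    thresh = np.empty(365)
    for d in range(365):
        if window_halfwidth:
            pool = np.concatenate(
                [by_day[(d + off) % 365] for off in range(-window_halfwidth, window_halfwidth + 1)]
            )
        else:
            pool = by_day[d]
        if pool.size == 0:
            mean[d] = np.nan
            thresh[d] = np.nan
            continue
        mean[d] = pool.mean()
        thresh[d] = np.percentile(pool, percentile)
    return DayClimatology(mean, thresh, percentile, window_halfwidth, n_years)


def _check_daily(dates) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(dates)
    if len(idx) > 1:
        gaps = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        if np.any(gaps != 1):
            raise ValueError("temperature series has gaps; fill or split first")
    return idx


def detect_events(
    dates,
    temps,
    clim: DayClimatology,
    *,
    min_duration: int = DEFAULT_MIN_DURATION,
    lake_id=None,
) -> list[HeatwaveEvent]:
    """Maximal runs of consecutive days with T strictly above threshold.

    Runs shorter than ``min_duration`` days are heat spikes, not events.
    Runs may cross calendar-year boundaries.  The series must be
    gap-free daily.
    """
    idx = _check_daily(dates)
    t = np.asarray(temps, dtype=float)
    thr = clim.threshold[doy_365(idx) - 1]
    hot = t > thr

    events: list[HeatwaveEvent] = []
    padded = np.concatenate([[False], hot, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive
    for s, e in zip(starts, ends):
        dur = e - s
        if dur < min_duration:
            continue
        events.append(
            HeatwaveEvent(
                start=idx[s],
                end=idx[e - 1],
                duration=int(dur),
                exceedance=float((t[s:e] - thr[s:e]).mean()),
                lake_id=lake_id,
            )
        )
    return events


def heatwave_day_mask(dates, events) -> np.ndarray:
    """Boolean mask over ``dates`` marking days inside any event."""
    idx = pd.DatetimeIndex(dates)
    mask = np.zeros(len(idx), dtype=bool)
    for ev in events:
        mask |= (idx >= ev.start) & (idx <= ev.end)
    return mask


def duration_stats(events, years) -> pd.DataFrame:
    """Annual total heatwave days plus their Theil–Sen trend.

    Returns a table (year, heatwave_days) with the trend attached in
    ``.attrs['trend_days_per_year']`` (days/year per year; an event
    spanning New Year contributes its days to each year it touches).
    """
    years = np.asarray(sorted(years))
    counts = {int(y): 0 for y in years}
    for ev in events:
        for day in pd.date_range(ev.start, ev.end, freq="D"):
            if day.year in counts:
                counts[day.year] += 1
    out = pd.DataFrame(
        {"year": list(counts), "heatwave_days": list(counts.values())}
    ).sort_values("year", ignore_index=True)
    slope = theil_sen(out["year"], out["heatwave_days"]) / 10.0 if len(out) >= 2 else float("nan")
    out.attrs["trend_days_per_year"] = slope
    return out


def _predict(predictor, features: pd.DataFrame) -> np.ndarray:
    # Accept either a fitted ModelBundle or any object with .predict(df).
    return np.asarray(predictor.predict(features), dtype=float)


def influence_intensity(
    predictor,
    features: pd.DataFrame,
    clim: DayClimatology,
    events,
    *,
    temp_col: str = "air_temperature",
    weighting: str = "day",
) -> InfluenceReport:
    """Instantaneous heatwave impact via counterfactual prediction.

    ``features`` is a date-indexed frame containing every model input for
    each heatwave day.  Each such day is predicted with actual
    temperature and again with that day's climatological mean; intensity
    is the signed percent difference normalised by the counterfactual.
    ``weighting='day'`` averages over heatwave days (default);
    ``'event'`` averages per-event means.
    """
    if not events:
        return InfluenceReport(float("nan"), float("nan"), [], 0)
    dates = pd.DatetimeIndex(features.index)
    mask = heatwave_day_mask(dates, events)
    hw = features.loc[mask].copy()
    if hw.empty:
        return InfluenceReport(float("nan"), float("nan"), [], 0)

    cf = hw.copy()
    cf[temp_col] = clim.mean_temp[doy_365(cf.index) - 1]
    do_actual = _predict(predictor, hw)
    do_clim = _predict(predictor, cf)
    ok = do_clim > 0
    rel = 100.0 * (do_actual[ok] - do_clim[ok]) / do_clim[ok]
    day_dates = pd.DatetimeIndex(hw.index)[ok]

    per_event = []
    for ev in events:
        in_ev = (day_dates >= ev.start) & (day_dates <= ev.end)
        if in_ev.any():
            per_event.append(float(rel[in_ev].mean()))
    if rel.size == 0:
        return InfluenceReport(float("nan"), float("nan"), per_event, 0)

    if weighting == "event":
        mean_int = float(np.mean(per_event))
    else:
        mean_int = float(rel.mean())
    max_int = float(rel[np.argmax(np.abs(rel))])
    return InfluenceReport(mean_int, max_int, per_event, int(rel.size))


def longterm_impact(
    predictor,
    features: pd.DataFrame,
    clim: DayClimatology,
    events,
    *,
    temp_col: str = "air_temperature",
) -> InfluenceReport:
    """Long-term heatwave impact: actual versus heatwave-free scenario.

    Scenario B replaces the temperature on every heatwave day with the
    day-specific climatological mean, all other features untouched.  The
    impact is ``100*(mean_A - mean_B)/mean_A`` over the full series, and
    both scenarios' annual-mean DO trends (per decade) are reported.
    """
    dates = pd.DatetimeIndex(features.index)
    do_a = _predict(predictor, features)
    if events:
        scen = features.copy()
        mask = heatwave_day_mask(dates, events)
        scen.loc[mask, temp_col] = clim.mean_temp[doy_365(dates[mask]) - 1]
        do_b = _predict(predictor, scen)
    else:
        do_b = do_a.copy()

    mean_a, mean_b = float(do_a.mean()), float(do_b.mean())
    impact = 100.0 * (mean_a - mean_b) / mean_a if mean_a != 0 else float("nan")

    ann = pd.DataFrame({"year": dates.year, "a": do_a, "b": do_b}).groupby("year").mean()
    rate_a = theil_sen(ann.index, ann["a"]) if len(ann) >= 2 else float("nan")
    rate_b = theil_sen(ann.index, ann["b"]) if len(ann) >= 2 else float("nan")

    rep = InfluenceReport(
        mean_intensity=float("nan"),
        max_intensity=float("nan"),
        n_heatwave_days=int(heatwave_day_mask(dates, events).sum()) if events else 0,
    )
    rep.longterm_mean_impact = impact
    rep.do_rate_actual = rate_a
    rep.do_rate_no_hw = rate_b
    return rep
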