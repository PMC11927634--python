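"""DO stress metrics and scenario-driven projection.

A lake is under *stress* when DO drops below 6.0 mg/L — the level at
which fish growth and food consumption decline measurably in fresh
water.  Per lake, the stress frequency is the percentage of time steps
(at whatever resolution the series carries) strictly below the
threshold; a *stressed lake* is one whose annual mean DO is below the
threshold.  Cohort-level output is the annual count of stressed lakes
and its trend per decade.

Projection applies a fitted DO model to scenario climate forcing from
an ensemble of members, with the two water-colour features frozen at
their means over the most recent five observed years (they cannot be
observed in the future).  The ensemble summary is the per-step mean
with a +/- 2 SD spread band across members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .do_model import ModelBundle, predict_series
from .trend_analysis import theil_sen

__all__ = [
    "STRESS_THRESHOLD",
    "stress_metrics",
    "cohort_stress",
    "freeze_watercolour",
    "project_do",
    "StressSummary",
    "ProjectionResult",
]

log = logging.getLogger(__name__)

STRESS_THRESHOLD = 6.0  # mg/L


@dataclass
class StressSummary:
    """Stress metrics for one lake's DO series."""

    frequency_pct: float           # % of steps with DO < threshold
    stressed_years: pd.Series      # year -> bool (annual mean < threshold)
    ever_stressed: bool
    resolution: str                # inferred time base of the series
    threshold: float = STRESS_THRESHOLD


def _infer_resolution(idx: pd.DatetimeIndex) -> str:
    if len(idx) < 2:
        return "unknown"
    step = np.median(np.diff(idx.values).astype("timedelta64[D]").astype(int))
    if step <= 1:
        return "daily"
    if step <= 31:
        return "monthly"
    return "annual"


def stress_metrics(dates, do, *, threshold: float = STRESS_THRESHOLD) -> StressSummary:
    """Stress frequency and stressed-lake flags for one DO series."""
    idx = pd.DatetimeIndex(dates)
    s = pd.Series(np.asarray(do, dtype=float), index=idx).dropna()
    if s.empty:
        return StressSummary(
            float("nan"), pd.Series(dtype=bool), False, "unknown", threshold
        )
    freq = 100.0 * float((s < threshold).mean())
    annual_mean = s.groupby(s.index.year).mean()
    stressed = annual_mean < threshold
    return StressSummary(
        frequency_pct=freq,
        stressed_years=stressed,
        ever_stressed=bool(stressed.any()),
        resolution=_infer_resolution(s.index),
        threshold=threshold,
    )


def cohort_stress(series_by_lake: dict, *, threshold: float = STRESS_THRESHOLD):
    """Cohort stress table: annual stressed-lake counts plus decade trend.

    ``series_by_lake`` maps lake_id -> (dates, do).  Returns
    (per_lake_frame, annual_counts_frame); the counts frame carries the
    Theil–Sen trend per decade in ``.attrs['count_trend_per_decade']``.
    """
    per_lake = []
    annual = {}
    for lake_id, (dates, do) in series_by_lake.items():
        summ = stress_metrics(dates, do, threshold=threshold)
        per_lake.append(
            {
                "lake_id": lake_id,
                "stress_frequency_pct": summ.frequency_pct,
                "ever_stressed": summ.ever_stressed,
            }
        )
        for year, flag in summ.stressed_years.items():
            annual[year] = annual.get(year, 0) + int(flag)
    counts = pd.DataFrame(
        {"year": sorted(annual), "n_stressed": [annual[y] for y in sorted(annual)]}
    )
    if len(counts) >= 2:
        counts.attrs["count_trend_per_decade"] = theil_sen(
            counts["year"], counts["n_stressed"]
        )
    else:
        counts.attrs["count_trend_per_decade"] = float("nan")
    return pd.DataFrame(per_lake), counts


def freeze_watercolour(
    features: pd.DataFrame,
    window_years: int = 5,
    *,
    columns=("fai", "hue_angle"),
) -> pd.Series | None:
    """Mean water-colour features over the trailing ``window_years`` years.

    ``features`` is a date-indexed historical frame for one lake.
    Returns a Series of frozen values, or None (logged) when the lake
    has no historical features at all.
    """
    cols = [c for c in columns if c in features.columns]
    hist = features[cols].dropna()
    if hist.empty:
        log.warning("no historical water-colour features; lake excluded")
        return None
    last = pd.DatetimeIndex(hist.index).max()
    cutoff = last - pd.DateOffset(years=window_years)
    window = hist.loc[pd.DatetimeIndex(hist.index) > cutoff]
    return window.mean()


@dataclass
class ProjectionResult:
    """Per-member projections with the ensemble summary for one lake."""

    members: dict                 # member_id -> predicted frame (do, do_sol, do_sp)
    ensemble: pd.DataFrame        # columns: do_mean, do_lo, do_hi (mean +/- 2 SD)
    member_trends: dict           # member_id -> mg/L per decade
    ensemble_trend: float         # mg/L per decade of the ensemble mean
    has_spread: bool


def project_do(
    bundle: ModelBundle,
    member_forcings: dict,
    frozen_colour: pd.Series,
    static_features: dict,
) -> ProjectionResult:
    """Project DO for one lake under an ensemble of scenario forcings.

    ``member_forcings`` maps member id -> date-indexed climate frame
    (with a ``wind_speed`` column or u/v components); water-colour
    features are held at ``frozen_colour`` and ``static_features``
    supplies elevation and absolute latitude.  Members missing required
    variables are dropped with a warning; with fewer than two surviving
    members no spread band is produced.
    """
    preds = {}
    trends = {}
    for member, forcing in member_forcings.items():
        f = forcing.copy()
        if "wind_speed" not in f.columns and {"wind_u", "wind_v"} <= set(f.columns):
            f["wind_speed"] = np.hypot(f["wind_u"], f["wind_v"])
        for col, val in frozen_colour.items():
            f[col] = val
        for col, val in static_features.items():
            f[col] = val
        missing = [c for c in bundle.features if c not in f.columns]
        if missing:
            log.warning("member %s missing %s; dropped", member, missing)
            continue
        pred = predict_series(bundle, f)
        preds[member] = pred
        ann = pred["do"].groupby(pd.DatetimeIndex(pred.index).year).mean()
        trends[member] = theil_sen(ann.index, ann.to_numpy()) if len(ann) >= 2 else float("nan")

    if not preds:
        raise ValueError("no ensemble member had complete forcing")

    stack = pd.concat({m: p["do"] for m, p in preds.items()}, axis=1)
    mean = stack.mean(axis=1)
    sd = stack.std(axis=1, ddof=0)
    has_spread = stack.shape[1] >= 2
    ensemble = pd.DataFrame(
        {
            "do_mean": mean,
            "do_lo": mean - 2.0 * sd if has_spread else mean,
            "do_hi": mean + 2.0 * sd if has_spread else mean,
        }
    )
    ann = mean.groupby(pd.DatetimeIndex(mean.index).year).mean()
    ens_trend = theil_sen(ann.index, ann.to_numpy()) if len(ann) >= 2 else float("nan")
    return ProjectionResult(preds, ensemble, trends, ens_trend, has_spread)
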