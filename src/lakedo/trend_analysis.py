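"""Hemisphere-aware annual aggregation and nonparametric trend tests.

Long-term analysis of reconstructed DO works on summer-only annual
medians — July–September in the Northern Hemisphere, January–March in
the Southern — so that snow/ice-affected observations never enter the
trend.  Trends are the Theil–Sen median of pairwise slopes, reported in
units per decade; significance is a two-sided Mann–Kendall test with
tie-corrected variance and continuity correction (exact null
distribution for short, tie-free series).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUMMER_MONTHS",
    "summer_months",
    "summer_annual_median",
    "theil_sen",
    "mann_kendall",
    "trend",
    "AnnualSeries",
    "TrendResult",
]

SUMMER_MONTHS = {"N": (7, 8, 9), "S": (1, 2, 3)}

# Switch to the exact Mann-Kendall null distribution at or below this n
# (cheap to enumerate; the normal approximation is weakest here).
EXACT_MK_MAX_N = 10


@dataclass
class AnnualSeries:
    """One value per year (summer median of some variable) for one lake."""

    years: np.ndarray
    values: np.ndarray
    hemisphere: str
    lake_id: object = None

    def __len__(self) -> int:
        return len(self.years)


@dataclass
class TrendResult:
    """Theil–Sen slope (per decade) with Mann–Kendall significance."""

    slope_per_decade: float
    intercept: float
    mk_s: int
    var_s: float
    p_value: float
    significant: bool
    n: int


def summer_months(hemisphere: str):
    """Summer month numbers for hemisphere tag 'N' or 'S'."""
    try:
        return SUMMER_MONTHS[hemisphere.upper()[0]]
    except (KeyError, IndexError, AttributeError):
        raise ValueError(f"unknown hemisphere tag: {hemisphere!r}") from None


def summer_annual_median(
    dates, values, hemisphere: str, lake_id=None
) -> AnnualSeries:
    """Per-year median over summer months only; empty years are dropped."""
    months = summer_months(hemisphere)
    s = pd.Series(
        np.asarray(values, dtype=float), index=pd.DatetimeIndex(dates)
    ).dropna()
    summer = s[s.index.month.isin(months)]
    med = summer.groupby(summer.index.year).median()
    return AnnualSeries(
        years=med.index.to_numpy(dtype=float),
        values=med.to_numpy(),
        hemisphere=hemisphere.upper()[0],
        lake_id=lake_id,
    )


def theil_sen(years, values) -> float:
    """Theil–Sen slope — the median of all pairwise slopes — per decade.

    Returns NaN for fewer than two points.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 2:
        return float("nan")
    slope = stats.theilslopes(y, t).slope
    return 10.0 * float(slope)


def _mk_s_and_var(y: np.ndarray) -> tuple[int, float]:
    # S = sum over i<j of sign(y_j - y_i); variance with tie correction.
    n = y.size
    diff = np.sign(y[None, :] - y[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0
    return s, float(var)


@lru_cache(maxsize=32)
def _exact_s_distribution(n: int) -> np.ndarray:
    # Counts of permutations of 1..n by number of non-inversions; index k
    # corresponds to P = k concordant pairs, S = 2k - n(n-1)/2.
    counts = np.array([1], dtype=float)
    for i in range(2, n + 1):
        new = np.zeros(len(counts) + i - 1)
        for k in range(i):  # inserting element i contributes 0..i-1 pairs
            new[k : k + len(counts)] += counts
        counts = new
    return counts / counts.sum()


def mann_kendall(years, values, alpha: float = 0.05) -> TrendResult:
    """Two-sided Mann–Kendall monotonic-trend test plus Theil–Sen slope.

    Normal approximation with continuity correction; for n <= 10 with no
    ties the exact permutation null of S is used instead.  All-tied
    series give S = 0, p = 1.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    order = np.argsort(t)
    t, y = t[order], y[order]
    n = y.size
    if n < 4:
        raise ValueError("Mann-Kendall requires at least 4 points")

    s, var = _mk_s_and_var(y)
    slope = theil_sen(t, y)
    intercept = float(np.median(y) - (slope / 10.0) * np.median(t)) if n else np.nan

    if var == 0:  # all values tied
        return TrendResult(slope, intercept, s, 0.0, 1.0, False, n)

    has_ties = np.unique(y).size < n
    if n <= EXACT_MK_MAX_N and not has_ties:
        dist = _exact_s_distribution(n)
        s_values = 2 * np.arange(len(dist)) - n * (n - 1) // 2
        p = float(dist[np.abs(s_values) >= abs(s)].sum())
        p = min(1.0, p)
    else:
        if s > 0:
            z = (s - 1) / np.sqrt(var)
        elif s < 0:
            z = (s + 1) / np.sqrt(var)
        else:
            z = 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
    return TrendResult(slope, intercept, s, var, p, p < alpha, n)


def trend(annual: AnnualSeries, alpha: float = 0.05) -> TrendResult:
    """Convenience: Mann–Kendall + Theil–Sen on an :class:`AnnualSeries`."""
    return mann_kendall(annual.years, annual.values, alpha=alpha)


def cohort_trends(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-lake trends from a tidy (lake_id, year, value) table."""
    rows = []
    for lake_id, grp in df.groupby("lake_id"):
        try:
            res = mann_kendall(grp["year"], grp["value"], alpha=alpha)
        except ValueError:
            continue
        rows.append(
            {
                "lake_id": lake_id,
                "slope_per_decade": res.slope_per_decade,
                "s": res.mk_s,
                "p": res.p_value,
                "significant": res.significant,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
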