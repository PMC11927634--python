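"""Standardized path-coefficient attribution of DO change.

A piecewise path model quantifies how long-term climate change routes
into DO through two mechanisms: solubility (temperature, wind and
pressure -> DOsol -> DO) and eutrophication (temperature -> FAI -> DO).
Per lake, annual series of the six variables are standardised to mean 0
and SD 1 and three least-squares sub-models are fitted::

    DOsol ~ T + wind + pressure
    FAI   ~ T
    DO    ~ DOsol + FAI

The standardised coefficients give the strength and sign of each arrow;
cohort summaries average them across lakes (reported as signed percent)
and count lakes by direction, with |coef| < 0.05 classed as negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "standardize",
    "fit_path_model",
    "mean_contributions",
    "rate_correlation",
    "PathModel",
    "ContributionSummary",
    "PATHS",
    "NEGLIGIBLE_THRESHOLD",
]

PATHS = (
    "t_to_dosol",
    "wind_to_dosol",
    "pressure_to_dosol",
    "t_to_fai",
    "dosol_to_do",
    "fai_to_do",
)

NEGLIGIBLE_THRESHOLD = 0.05


@dataclass
class PathModel:
    """Standardized path coefficients for one lake."""

    t_to_dosol: float
    wind_to_dosol: float
    pressure_to_dosol: float
    t_to_fai: float
    dosol_to_do: float
    fai_to_do: float
    n_years: int
    lake_id: object = None
    zero_variance: list = field(default_factory=list)

    def coefficient(self, path: str) -> float:
        return getattr(self, path)

    def direction(self, path: str) -> str:
        c = self.coefficient(path)
        if abs(c) < NEGLIGIBLE_THRESHOLD:
            return "negligible"
        return "positive" if c > 0 else "negative"


@dataclass
class ContributionSummary:
    """Cohort aggregation of per-lake path models."""

    mean_contribution_pct: dict   # path -> mean standardized coef x 100
    direction_counts: dict        # path -> {positive, negative, negligible}
    n_lakes: int


def standardize(x) -> np.ndarray:
    """Mean-0, SD-1 standardisation; zero-variance input comes back all-zero."""
    v = np.asarray(x, dtype=float)
    sd = v.std()
    # exact-constant input can leave a rounding-level sd; treat as zero
    if sd == 0 or np.all(v == v[0]):
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _ols_coefs(y: np.ndarray, xs: list[np.ndarray]) -> np.ndarray:
    design = np.column_stack(xs)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def fit_path_model(annual: pd.DataFrame, lake_id=None) -> PathModel:
    """Fit the three standardized sub-models for one lake.

    ``annual`` needs columns (do, dosol, fai, t, wind, pressure) with one
    row per year, at least 10 years.  Variables with zero variance have
    all their incident paths set to 0 and are flagged.
    """
    required = ["do", "dosol", "fai", "t", "wind", "pressure"]
    missing = [c for c in required if c not in annual.columns]
    if missing:
        raise KeyError(f"missing column(s): {missing}")
    df = annual[required].dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 annual values, got {len(df)}")

    zero_var = [c for c in required if df[c].std() == 0]
    z = {c: standardize(df[c]) for c in required}

    def coefs(target, predictors):
        if target in zero_var:
            return np.zeros(len(predictors))
        out = _ols_coefs(z[target], [z[p] for p in predictors])
        return np.where([p in zero_var for p in predictors], 0.0, out)

    b_sol = coefs("dosol", ["t", "wind", "pressure"])
    b_fai = coefs("fai", ["t"])
    b_do = coefs("do", ["dosol", "fai"])

    return PathModel(
        t_to_dosol=float(b_sol[0]),
        wind_to_dosol=float(b_sol[1]),
        pressure_to_dosol=float(b_sol[2]),
        t_to_fai=float(b_fai[0]),
        dosol_to_do=float(b_do[0]),
        fai_to_do=float(b_do[1]),
        n_years=len(df),
        lake_id=lake_id,
        zero_variance=zero_var,
    )


def mean_contributions(models) -> ContributionSummary:
    """Cohort mean path contributions (signed percent) and direction counts."""
    models = list(models)
    if not models:
        raise ValueError("need at least one path model")
    mean_pct = {}
    counts = {}
    for path in PATHS:
        vals = np.array([m.coefficient(path) for m in models], dtype=float)
        mean_pct[path] = float(100.0 * vals.mean())
        dirs = [m.direction(path) for m in models]
        counts[path] = {
            "positive": dirs.count("positive"),
            "negative": dirs.count("negative"),
            "negligible": dirs.count("negligible"),
        }
    return ContributionSummary(mean_pct, counts, len(models))


def models_frame(models) -> pd.DataFrame:
    """Tidy per-lake coefficient table."""
    rows = []
    for m in models:
        d = {p: m.coefficient(p) for p in PATHS}
        d["lake_id"] = m.lake_id
        d["n_years"] = m.n_years
        rows.append(d)
    return pd.DataFrame(rows)


def rate_correlation(rates_a, rates_b):
    """Pearson correlation (R, two-sided p) between paired per-lake rates."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a[ok], b[ok])
    return float(r), float(p)
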