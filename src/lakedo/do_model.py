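"""Matchup assembly, feature scaling, and the tree-ensemble DO regressor.

The reconstruction model maps ten features — six climate variables (air
temperature, pressure, solar and thermal radiation, precipitation, wind
speed from its u/v components), two water-colour indices (FAI, hue
angle) and two static geographic factors (elevation, absolute latitude)
— to surface DO (mg/L).  Training rows are *matchups*: in situ DO
observations paired with climate records within 1 hour and reflectance
samples within 2 days, reflectance features being 3x3-window means that
passed the coefficient-of-variation gate upstream.

The production model is a random forest; a gradient-boosting
alternative is retained for comparison runs.  Features are standardised
(mean 0, SD 1) then min–max rescaled to [0, 1], both fitted on training
rows only; test rows outside the training range scale outside [0, 1]
and are deliberately not clipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV

from . import oxygen_physics
from .synthetic_data import SOLUBILITY_T_CLIP

__all__ = [
    "FEATURES",
    "DEFAULT_GRID",
    "build_matchups",
    "FeatureScaler",
    "fit_model",
    "evaluate",
    "predict_series",
    "train_test_split_rows",
    "ModelBundle",
    "EvalReport",
    "SolubilityPredictor",
]

log = logging.getLogger(__name__)

FEATURES = [
    "air_temperature",
    "pressure",
    "solar",
    "thermal",
    "precip",
    "wind_speed",
    "fai",
    "hue_angle",
    "elevation",
    "abs_latitude",
]

# Hyperparameter grid searched by default; a single-point grid skips the
# cross-validated search entirely.
DEFAULT_GRID = {
    "n_estimators": [200, 500],
    "max_depth": [10, 20, None],
    "min_samples_leaf": [1, 5],
}

CLIMATE_WINDOW = pd.Timedelta(hours=1)
REFLECTANCE_WINDOW = pd.Timedelta(days=2)


def wind_speed(u, v):
    """Scalar wind speed from the u/v components."""
    return np.hypot(np.asarray(u, dtype=float), np.asarray(v, dtype=float))


def _nearest_within(times: np.ndarray, targets: np.ndarray, window_ns: int):
    """Index of the record nearest to each target within the window.

    Ties on absolute gap go to the earlier record.  ``times`` must be
    sorted int64 nanoseconds.  Returns an int index array with -1 where
    nothing qualifies.
    """
    pos = np.searchsorted(times, targets)
    left = np.clip(pos - 1, 0, len(times) - 1)
    right = np.clip(pos, 0, len(times) - 1)
    gap_left = np.abs(times[left] - targets)
    gap_right = np.abs(times[right] - targets)
    # equal gaps resolve to the earlier (left) record
    take_left = gap_left <= gap_right
    best = np.where(take_left, left, right)
    best_gap = np.where(take_left, gap_left, gap_right)
    return np.where(best_gap <= window_ns, best, -1)


def build_matchups(
    obs: pd.DataFrame,
    climate: pd.DataFrame,
    reflectance_features: pd.DataFrame,
    lake_meta: pd.DataFrame | None = None,
    *,
    climate_window: pd.Timedelta = CLIMATE_WINDOW,
    reflectance_window: pd.Timedelta = REFLECTANCE_WINDOW,
) -> pd.DataFrame:
    """Pair in situ DO observations with climate and reflectance records.

    Parameters
    ----------
    obs : frame with columns (lake_id, time, do_obs)
    climate : frame with (lake_id, time, air_temperature, pressure, solar,
        thermal, precip, wind_u, wind_v)
    reflectance_features : frame with (lake_id, time, fai, hue_angle),
        pre-filtered by the window CV gate
    lake_meta : optional frame indexed by lake_id with (latitude, elevation)
        supplying the static features

    One row per observation satisfying both time windows (climate within
    1 h, reflectance within 2 d); nearest record wins, earlier on ties.
    Returns an empty table (with a warning) when nothing matches.
    """
    clim_groups = {k: g.sort_values("time") for k, g in climate.groupby("lake_id")}
    refl_groups = {
        k: g.sort_values("time") for k, g in reflectance_features.groupby("lake_id")
    }
    clim_cols = [c for c in climate.columns if c not in ("lake_id", "time")]

    pieces = []
    for lake_id, g_obs in obs.groupby("lake_id"):
        g_clim = clim_groups.get(lake_id)
        g_refl = refl_groups.get(lake_id)
        if g_clim is None or g_refl is None or g_clim.empty or g_refl.empty:
            continue
        ct = g_clim["time"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        rt = g_refl["time"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        ot = g_obs["time"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        ci = _nearest_within(ct, ot, climate_window.value)
        ri = _nearest_within(rt, ot, reflectance_window.value)
        ok = (ci >= 0) & (ri >= 0)
        if not ok.any():
            continue
        ci, ri = ci[ok], ri[ok]
        piece = pd.DataFrame(
            {
                "lake_id": lake_id,
                "time": g_obs["time"].to_numpy()[ok],
                "do_obs": g_obs["do_obs"].to_numpy()[ok],
                "t_climate": g_clim["time"].to_numpy()[ci],
                "t_reflectance": g_refl["time"].to_numpy()[ri],
                "fai": g_refl["fai"].to_numpy()[ri],
                "hue_angle": g_refl["hue_angle"].to_numpy()[ri],
            }
        )
        for c in clim_cols:
            piece[c] = g_clim[c].to_numpy()[ci]
        pieces.append(piece)

    out = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
    if out.empty:
        warnings.warn("no qualifying matchups found")
        return out
    if "wind_u" in out.columns:
        out["wind_speed"] = wind_speed(out["wind_u"], out["wind_v"])
    if lake_meta is not None:
        out["elevation"] = out["lake_id"].map(lake_meta["elevation"]).astype(float)
        out["abs_latitude"] = (
            out["lake_id"].map(lake_meta["latitude"]).abs().astype(float)
        )
    return out


class FeatureScaler:
    """Standardise then min–max rescale to [0, 1], fitted on training rows.

    Zero-variance features standardise to 0 and land at 0.5 (with a
    warning).  ``inverse_transform`` round-trips exactly for
    non-degenerate features; out-of-range rows map outside [0, 1] and
    are preserved unclipped.
    """

    def __init__(self, columns):
        self.columns = list(columns)

    def fit(self, df: pd.DataFrame) -> "FeatureScaler":
        if len(df) == 0:
            raise ValueError("cannot fit a scaler on zero rows")
        x = df[self.columns].to_numpy(dtype=float)
        self.mean_ = x.mean(axis=0)
        self.sd_ = x.std(axis=0)
        degenerate = self.sd_ == 0
        if degenerate.any():
            bad = [c for c, d in zip(self.columns, degenerate) if d]
            warnings.warn(f"zero-variance feature(s) pinned at 0.5: {bad}")
        self.sd_ = np.where(degenerate, 1.0, self.sd_)
        z = (x - self.mean_) / self.sd_
        self.zmin_ = z.min(axis=0)
        self.zmax_ = z.max(axis=0)
        span = self.zmax_ - self.zmin_
        self.degenerate_ = span == 0
        self.span_ = np.where(self.degenerate_, 1.0, span)
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        z = (df[self.columns].to_numpy(dtype=float) - self.mean_) / self.sd_
        scaled = (z - self.zmin_) / self.span_
        return np.where(self.degenerate_, 0.5, scaled)

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        z = np.asarray(scaled, dtype=float) * self.span_ + self.zmin_
        return z * self.sd_ + self.mean_


@dataclass
class ModelBundle:
    """Fitted regressor plus its scaler and training metadata."""

    model: object
    scaler: FeatureScaler
    features: list
    seed: int
    n_train: int
    train_ids: frozenset
    best_params: dict
    train_metrics: "EvalReport"
    degenerate_target: bool = False

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.features if c not in df.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        return self.model.predict(self.scaler.transform(df))

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        import joblib

        return joblib.load(path)


@dataclass
class EvalReport:
    """MAE / MRE / RMSE / R-squared on a labelled table."""

    mae: float
    mre: float
    rmse: float
    r2: float
    n: int
    n_excluded_mre: int = 0

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mre": self.mre,
            "rmse": self.rmse,
            "r2": self.r2,
            "n": self.n,
        }


def _metrics(y: np.ndarray, yhat: np.ndarray) -> EvalReport:
    err = yhat - y
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    nz = y != 0
    mre = float((np.abs(err[nz]) / np.abs(y[nz])).mean()) if nz.any() else float("nan")
    ss_res = float((err**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return EvalReport(mae, mre, rmse, r2, len(y), int((~nz).sum()))


def train_test_split_rows(table: pd.DataFrame, *, test_frac: float = 0.30, seed: int = 42):
    """Random row split (default 70/30) returning (train, test) frames."""
    rng = np.random.default_rng(seed)
    n = len(table)
    test_idx = rng.choice(n, size=int(round(test_frac * n)), replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    return table.loc[~mask], table.loc[mask]


def fit_model(
    train_table: pd.DataFrame,
    grid: dict | None = None,
    seed: int = 42,
    *,
    target: str = "do_obs",
    features=None,
    model: str = "rf",
    cv: int = 3,
) -> ModelBundle:
    """Fit the tree-ensemble DO regressor with a grid-searched setup.

    ``model='rf'`` (production) or ``'gbm'`` (comparison).  A grid with a
    single combination is fitted directly without cross-validation.
    Deterministic under a fixed seed.  A constant training target is
    fitted but flagged.
    """
    features = list(features or FEATURES)
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRID)
    scaler = FeatureScaler(features).fit(train_table)
    x = scaler.transform(train_table)
    y = train_table[target].to_numpy(dtype=float)

    degenerate = bool(np.all(y == y[0])) if len(y) else True
    if degenerate:
        log.warning("training target is constant; model flagged degenerate")

    if model == "rf":
        base = RandomForestRegressor(random_state=seed, n_jobs=1)
    elif model == "gbm":
        base = GradientBoostingRegressor(random_state=seed)
        grid = {k: v for k, v in grid.items() if k in base.get_params()}
    else:
        raise ValueError(f"unknown model kind: {model!r}")

    n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_combos > 1:
        search = GridSearchCV(
            base, grid, cv=cv, scoring="neg_mean_absolute_error", n_jobs=1
        )
        search.fit(x, y)
        est = search.best_estimator_
        best = dict(search.best_params_)
    else:
        params = {k: v[0] for k, v in grid.items()}
        est = base.set_params(**params)
        est.fit(x, y)
        best = params

    train_metrics = _metrics(y, est.predict(x))
    return ModelBundle(
        model=est,
        scaler=scaler,
        features=features,
        seed=seed,
        n_train=len(y),
        train_ids=frozenset(train_table.index),
        best_params=best,
        train_metrics=train_metrics,
        degenerate_target=degenerate,
    )


def evaluate(bundle: ModelBundle, test_table: pd.DataFrame, *, target: str = "do_obs") -> EvalReport:
    """Held-out metrics; refuses test rows that overlap the training rows."""
    overlap = bundle.train_ids.intersection(test_table.index)
    if overlap:
        raise ValueError(
            f"{len(overlap)} test row id(s) overlap the training set (leakage)"
        )
    y = test_table[target].to_numpy(dtype=float)
    yhat = bundle.predict(test_table)
    return _metrics(y, yhat)


class SolubilityPredictor:
    """Physics-only DO predictor: DO = solubility(T, P), nothing else.

    A closed-form stand-in for a fitted model wherever a counterfactual
    or projection result must be checkable analytically against the
    solubility curve.  Duck-types the ``predict``/``features`` surface
    of :class:`ModelBundle`.
    """

    features = ["air_temperature", "pressure"]

    def __init__(self, temp_col: str = "air_temperature", pressure_col: str = "pressure"):
        self.temp_col = temp_col
        self.pressure_col = pressure_col

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        t = np.clip(df[self.temp_col].to_numpy(dtype=float), *SOLUBILITY_T_CLIP)
        p = df[self.pressure_col].to_numpy(dtype=float) if self.pressure_col in df else 1.0
        return np.asarray(oxygen_physics.solubility(t, p))


def predict_series(
    bundle: ModelBundle,
    features: pd.DataFrame,
    *,
    pressure_col: str = "pressure",
    temp_col: str = "air_temperature",
) -> pd.DataFrame:
    """Predict a DO series with companion solubility and saturation departure.

    ``features`` is date-indexed with every model input present; rows
    with missing values are skipped and logged.  Output columns:
    ``do`` (mg/L), ``do_sol`` (mg/L), ``do_sp`` (percent).
    """
    complete = features[bundle.features].notna().all(axis=1)
    n_skip = int((~complete).sum())
    if n_skip:
        log.info("skipping %d rows with missing features", n_skip)
    sub = features.loc[complete]
    do = bundle.predict(sub)
    t = np.clip(sub[temp_col].to_numpy(dtype=float), *SOLUBILITY_T_CLIP)
    dosol = oxygen_physics.solubility(t, sub[pressure_col].to_numpy(dtype=float))
    dsp = oxygen_physics.do_sp(do, dosol)
    return pd.DataFrame(
        {"do": do, "do_sol": dosol, "do_sp": dsp}, index=sub.index
    )
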