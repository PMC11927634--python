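"""End-to-end orchestration: simulate -> features -> model -> analyses.

``run_end_to_end`` drives the whole reconstruction-and-attribution
chain on a synthetic cohort under a single config with one seed:

1. **simulate** — lakes, daily forcing (baseline 1970–1999 through the
   study period), latent trophic state, reflectance, true DO, surveys;
2. **features** — FAI and hue angle from the reflectance samples;
3. **fit** — matchup assembly (1 h / 2 d windows), 70/30 split, the
   tree-ensemble regressor, held-out evaluation;
4. **predict** — DO reconstruction (with solubility and saturation
   departure) on every reflectance date;
5. **trend** — summer annual medians, Theil–Sen slopes per decade,
   Mann–Kendall significance, for DO / DOsol / FAI;
6. **heatwave** — day-specific percentile climatology, event detection,
   counterfactual influence intensities, long-term impact;
7. **attribution** — per-lake standardized path models and cohort
   contributions, plus the DO-rate vs DOsol-rate correlation;
8. **stress** — stress frequency and stressed-lake counts;
9. **project** — scenario forcing ensembles with frozen water colour.

Outputs are plain CSV/JSON in the configured directory plus a JSON run
manifest carrying the config hash, stage row counts, headline summary
numbers and a sha256 per output file.  The manifest contains no wall
time, so identical config + seed reproduces byte-identical output.
Daily forcing and truth tables are written as monthly aggregates to
keep run directories desk-sized; every sparse table is written in full.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    attribution,
    do_model,
    heatwave,
    oxygen_physics,
    stress_projection,
    synthetic_data,
    trend_analysis,
    water_optics,
)
from .synthetic_data import SyntheticConfig

__all__ = ["PipelineConfig", "validate_config", "run_end_to_end", "STAGES"]

log = logging.getLogger("lakedo.pipeline")

STAGES = (
    "simulate",
    "features",
    "fit",
    "predict",
    "trend",
    "heatwave",
    "attribution",
    "stress",
    "project",
)

# Scenario warming rates (degC per decade) used for mock ensemble forcing;
# the stronger scenario warms ~2.3x faster than the moderate one.
DEFAULT_SCENARIOS = {"ssp245": 0.3, "ssp585": 0.7}


@dataclass
class PipelineConfig:
    """Single config for the full pipeline; defaults are the study constants.

    Heatwaves: 90th day-specific percentile of the 1970–1999 baseline,
    >= 5-day persistence.  Stress: 6.0 mg/L.  Summers: Jul–Sep (N),
    Jan–Mar (S).  Trend significance at alpha = 0.05.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    seed: int = 42
    alpha: float = 0.05
    heatwave_percentile: float = 90.0
    heatwave_min_duration: int = 5
    percentile_window_halfwidth: int = 0
    stress_threshold: float = 6.0
    freeze_window_years: int = 5
    test_frac: float = 0.30
    rf_grid: dict = field(
        default_factory=lambda: {
            "n_estimators": [100],
            "max_depth": [20],
            "min_samples_leaf": [2],
        }
    )
    longterm_impact_max_lakes: int = 20
    scenarios: dict = field(default_factory=lambda: dict(DEFAULT_SCENARIOS))
    n_members: int = 2
    projection_end_year: int = 2060
    outdir: str = "lakedo_run"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
            syn_unknown = set(d["synthetic"]) - syn_known
            if syn_unknown:
                raise ValueError(
                    f"unknown synthetic config key(s): {sorted(syn_unknown)}"
                )
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d["outdir"] = None  # location-independent hash
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def validate_config(cfg: PipelineConfig):
    """Itemised error/warning lists; never raises on content."""
    errors, warnings_ = [], []
    try:
        cfg.synthetic.validate()
    except Exception as exc:
        errors.append(str(exc))
    if not (0 < cfg.heatwave_percentile <= 100):
        errors.append(f"heatwave_percentile out of range: {cfg.heatwave_percentile}")
    if cfg.heatwave_min_duration < 1:
        errors.append("heatwave_min_duration must be >= 1")
    elif cfg.heatwave_min_duration != 5:
        warnings_.append(
            "heatwave_min_duration deviates from the 5-day persistence default"
        )
    if not (0 < cfg.alpha < 1):
        errors.append(f"alpha out of range: {cfg.alpha}")
    if cfg.stress_threshold <= 0:
        errors.append("stress_threshold must be > 0")
    if not (0 < cfg.test_frac < 1):
        errors.append("test_frac must be in (0, 1)")
    if cfg.n_members < 2:
        warnings_.append("fewer than 2 ensemble members: no spread band")
    unknown_stages = set(cfg.stages) - set(STAGES)
    if unknown_stages:
        errors.append(f"unknown stage(s): {sorted(unknown_stages)}")
    return errors, warnings_


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.6g", **kw)


def _noon_times(dates: pd.DatetimeIndex) -> pd.Series:
    return pd.Series(dates + pd.Timedelta(hours=12))


def run_end_to_end(cfg: PipelineConfig) -> dict:
    """Run every enabled stage; returns (and writes) the run manifest."""
    errors, warns = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    for w in warns:
        log.warning(w)

    outdir = Path(cfg.outdir)
    created_outdir = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lakedo")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
    enabled = {s: bool(cfg.stages.get(s, True)) for s in STAGES}
    manifest: dict = {
        "config": cfg.canonical_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "created_outdir": created_outdir,
        "stages": {},
        "summary": {},
        "outputs": {},
    }
    state: dict = {}

    try:
        if enabled["simulate"]:
            _stage_simulate(syn, cfg, state, outdir, manifest)
        else:
            manifest["stages"]["simulate"] = {"status": "skipped"}
        for stage, fn in (
            ("features", _stage_features),
            ("fit", _stage_fit),
            ("predict", _stage_predict),
            ("trend", _stage_trend),
            ("heatwave", _stage_heatwave),
            ("attribution", _stage_attribution),
            ("stress", _stage_stress),
            ("project", _stage_project),
        ):
            if not enabled[stage]:
                manifest["stages"][stage] = {"status": "skipped"}
                continue
            _require(stage, state, manifest)
            try:
                fn(syn, cfg, state, outdir, manifest)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    for path in sorted(outdir.glob("*")):
        if path.name not in ("manifest.json",):
            manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            _json_safe(manifest), fh, indent=2, sort_keys=True, allow_nan=False
        )
    return manifest


def _json_safe(obj):
    """JSON-serialisable copy: NaN/inf -> None, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (str, int, bool)) or obj is None:
        return obj
    return str(obj)


_STAGE_NEEDS = {
    "features": ["reflectance"],
    "fit": ["features", "obs", "climate_study"],
    "predict": ["bundle", "features", "climate_study"],
    "trend": ["predictions"],
    "heatwave": ["bundle", "climatology", "features"],
    "attribution": ["predictions", "climate_study", "features"],
    "stress": ["predictions"],
    "project": ["bundle", "features"],
}


def _require(stage: str, state: dict, manifest: dict) -> None:
    missing = [k for k in _STAGE_NEEDS.get(stage, []) if k not in state]
    if missing:
        raise StageError(
            stage,
            RuntimeError(
                f"requires upstream product(s) {missing}; an earlier stage was "
                "skipped or failed"
            ),
        )


def _stage_simulate(syn, cfg, state, outdir, manifest):
    try:
        lakes = synthetic_data.make_lakes(syn)
        lake_meta = synthetic_data.lakes_frame(lakes)
        study = syn.study_dates()
        clim_start = pd.Timestamp(syn.climatology_start)
        clim_end = pd.Timestamp(syn.climatology_end)

        climate_study, reflectance, truth, obs = {}, {}, {}, {}
        climatology, events_by_lake = {}, {}
        for lk in lakes:
            full = synthetic_data.make_climate(lk, syn)
            base = full.loc[clim_start:clim_end]
            climatology[lk.lake_id] = heatwave.day_climatology(
                base.index,
                base["air_temperature"].to_numpy(),
                percentile=cfg.heatwave_percentile,
                window_halfwidth=cfg.percentile_window_halfwidth,
            )
            cs = full.loc[study[0] : study[-1]]
            climate_study[lk.lake_id] = cs
            events_by_lake[lk.lake_id] = heatwave.detect_events(
                cs.index,
                cs["air_temperature"].to_numpy(),
                climatology[lk.lake_id],
                min_duration=cfg.heatwave_min_duration,
                lake_id=lk.lake_id,
            )
            troph = synthetic_data.make_trophic(lk, syn, cs.index)
            reflectance[lk.lake_id] = synthetic_data.make_reflectance(lk, syn, troph)
            tr = synthetic_data.make_true_do(lk, cs, troph, syn)
            truth[lk.lake_id] = tr
            obs[lk.lake_id] = synthetic_data.make_observations(lk, tr, syn)

        state.update(
            lakes=lakes,
            lake_meta=lake_meta,
            climate_study=climate_study,
            reflectance=reflectance,
            truth=truth,
            obs=obs,
            climatology=climatology,
            events=events_by_lake,
        )

        _write_csv(lake_meta, outdir / "lakes.csv")
        clim_monthly = pd.concat(
            {
                k: v.drop(columns="heatwave_flag").resample("MS").mean()
                for k, v in climate_study.items()
            },
            names=["lake_id", "date"],
        )
        _write_csv(clim_monthly, outdir / "climate_monthly.csv")
        truth_monthly = pd.concat(
            {
                k: v[["true_do", "do_sol", "latent_trophic"]].resample("MS").mean()
                for k, v in truth.items()
            },
            names=["lake_id", "date"],
        )
        _write_csv(truth_monthly, outdir / "truth_monthly.csv")
        refl_all = pd.concat(reflectance, names=["lake_id", "date"])
        _write_csv(refl_all, outdir / "reflectance.csv")
        obs_all = pd.concat(obs, names=["lake_id", "row"])
        _write_csv(obs_all.reset_index(level=1, drop=True), outdir / "observations.csv")

        manifest["stages"]["simulate"] = {
            "status": "ok",
            "n_lakes": len(lakes),
            "n_reflectance_samples": int(sum(len(v) for v in reflectance.values())),
            "n_observations": int(sum(len(v) for v in obs.values())),
        }
        log.info("simulate: %d lakes", len(lakes))
    except Exception as exc:
        raise StageError("simulate", exc) from exc


def _stage_features(syn, cfg, state, outdir, manifest):
    feats = {}
    for lake_id, refl in state["reflectance"].items():
        f = pd.DataFrame(index=refl.index)
        f["fai"] = water_optics.fai(refl["r_nir"], refl["r_red"], refl["r_swir"])
        chrom = water_optics.hue_angle(refl["r_red"], refl["r_green"], refl["r_blue"])
        f["hue_angle"] = chrom.a_prime
        feats[lake_id] = f
    state["features"] = feats
    all_f = pd.concat(feats, names=["lake_id", "date"])
    _write_csv(all_f, outdir / "watercolour_features.csv")
    manifest["stages"]["features"] = {"status": "ok", "n_rows": int(len(all_f))}


def _stage_fit(syn, cfg, state, outdir, manifest):
    lake_meta = state["lake_meta"]
    obs_tidy = pd.concat(
        [df.assign(lake_id=k) for k, df in state["obs"].items()], ignore_index=True
    )
    clim_tidy = pd.concat(
        [
            df.drop(columns="heatwave_flag")
            .reset_index(names="date")
            .assign(lake_id=k, time=lambda d: d["date"] + pd.Timedelta(hours=12))
            .drop(columns="date")
            for k, df in state["climate_study"].items()
        ],
        ignore_index=True,
    )
    refl_tidy = pd.concat(
        [
            df.reset_index(names="date")
            .assign(lake_id=k, time=lambda d: d["date"] + pd.Timedelta(hours=12))
            .drop(columns="date")
            for k, df in state["features"].items()
        ],
        ignore_index=True,
    )
    matchups = do_model.build_matchups(obs_tidy, clim_tidy, refl_tidy, lake_meta)
    if matchups.empty:
        raise RuntimeError("no matchups generated")
    train, test = do_model.train_test_split_rows(
        matchups, test_frac=cfg.test_frac, seed=cfg.seed
    )
    bundle = do_model.fit_model(train, grid=cfg.rf_grid, seed=cfg.seed)
    report = do_model.evaluate(bundle, test)
    state.update(matchups=matchups, bundle=bundle)

    _write_csv(matchups, outdir / "matchups.csv", index=False)
    bundle.save(outdir / "model.joblib")
    eval_blob = {
        "train": bundle.train_metrics.as_dict(),
        "test": report.as_dict(),
        "best_params": bundle.best_params,
        "n_train": bundle.n_train,
        "n_test": report.n,
    }
    with open(outdir / "model_eval.json", "w") as fh:
        json.dump(eval_blob, fh, indent=2, sort_keys=True)
    manifest["stages"]["fit"] = {
        "status": "ok",
        "n_matchups": int(len(matchups)),
        "n_train": bundle.n_train,
        "n_test": report.n,
    }
    manifest["summary"]["model_test"] = report.as_dict()
    log.info(
        "fit: %d matchups, test MAE %.3f R2 %.3f", len(matchups), report.mae, report.r2
    )


def _lake_static(lake) -> dict:
    return {"elevation": lake.elevation, "abs_latitude": abs(lake.latitude)}


def _prediction_features(state, lake) -> pd.DataFrame:
    """Model inputs on reflectance dates: climate + water colour + static."""
    cs = state["climate_study"][lake.lake_id]
    f = state["features"][lake.lake_id]
    x = cs.loc[cs.index.isin(f.index)].drop(columns="heatwave_flag").copy()
    x["wind_speed"] = np.hypot(x["wind_u"], x["wind_v"])
    x = x.join(f)
    for k, v in _lake_static(lake).items():
        x[k] = v
    return x


def _stage_predict(syn, cfg, state, outdir, manifest):
    preds = {}
    for lk in state["lakes"]:
        x = _prediction_features(state, lk)
        preds[lk.lake_id] = do_model.predict_series(state["bundle"], x)
    state["predictions"] = preds
    all_p = pd.concat(preds, names=["lake_id", "date"])
    _write_csv(all_p, outdir / "predictions.csv")
    manifest["stages"]["predict"] = {"status": "ok", "n_rows": int(len(all_p))}
    manifest["summary"]["mean_do_mg_l"] = float(all_p["do"].mean())
    manifest["summary"]["sd_do_mg_l"] = float(all_p["do"].std(ddof=0))


def _annual_summer(series_index, values, hemisphere):
    return trend_analysis.summer_annual_median(series_index, values, hemisphere)


def _stage_trend(syn, cfg, state, outdir, manifest):
    rows = []
    annual_frames = []
    for lk in state["lakes"]:
        p = state["predictions"][lk.lake_id]
        f = state["features"][lk.lake_id]
        for var, (idx, vals) in {
            "do": (p.index, p["do"]),
            "dosol": (p.index, p["do_sol"]),
            "fai": (f.index, f["fai"]),
        }.items():
            ann = _annual_summer(idx, np.asarray(vals, dtype=float), lk.hemisphere)
            if len(ann) < 4:
                continue
            res = trend_analysis.trend(ann, alpha=cfg.alpha)
            rows.append(
                {
                    "lake_id": lk.lake_id,
                    "variable": var,
                    "slope_per_decade": res.slope_per_decade,
                    "s": res.mk_s,
                    "p": res.p_value,
                    "significant": res.significant,
                    "n_years": res.n,
                }
            )
            annual_frames.append(
                pd.DataFrame(
                    {
                        "lake_id": lk.lake_id,
                        "variable": var,
                        "year": ann.years.astype(int),
                        "value": ann.values,
                    }
                )
            )
    trends = pd.DataFrame(rows)
    state["trends"] = trends
    _write_csv(trends, outdir / "trends.csv", index=False)
    _write_csv(
        pd.concat(annual_frames, ignore_index=True), outdir / "annual_summer.csv",
        index=False,
    )
    do_tr = trends.query("variable == 'do'")["slope_per_decade"]
    manifest["stages"]["trend"] = {"status": "ok", "n_lakes": int(len(do_tr))}
    manifest["summary"]["median_do_trend_mg_l_per_decade"] = float(do_tr.median())
    manifest["summary"]["pct_lakes_declining"] = float(100.0 * (do_tr < 0).mean())


def _stage_heatwave(syn, cfg, state, outdir, manifest):
    bundle = state["bundle"]
    ev_rows, impact_rows = [], []
    annual_days = []
    for i, lk in enumerate(state["lakes"]):
        events = state["events"][lk.lake_id]
        clim = state["climatology"][lk.lake_id]
        cs = state["climate_study"][lk.lake_id]
        for ev in events:
            ev_rows.append(
                {
                    "lake_id": lk.lake_id,
                    "start": ev.start.date(),
                    "end": ev.end.date(),
                    "duration": ev.duration,
                    "exceedance": ev.exceedance,
                }
            )
        years = sorted(set(cs.index.year))
        days = heatwave.duration_stats(events, years)
        days["lake_id"] = lk.lake_id
        annual_days.append(days)

        # daily features with water colour filled from the nearest sample
        f = state["features"][lk.lake_id]
        x = cs.drop(columns="heatwave_flag").copy()
        x["wind_speed"] = np.hypot(x["wind_u"], x["wind_v"])
        if len(f):
            filled = f.reindex(x.index, method="nearest")
        else:
            filled = pd.DataFrame(index=x.index, columns=f.columns, dtype=float)
        x = x.join(filled)
        for k, v in _lake_static(lk).items():
            x[k] = v

        inst = heatwave.influence_intensity(bundle, x, clim, events)
        row = {
            "lake_id": lk.lake_id,
            "n_events": len(events),
            "n_heatwave_days": inst.n_heatwave_days,
            "mean_intensity_pct": inst.mean_intensity,
            "max_intensity_pct": inst.max_intensity,
            "heatwave_days_per_year": (
                sum(e.duration for e in events) / max(len(years), 1)
            ),
        }
        if i < cfg.longterm_impact_max_lakes:
            lt = heatwave.longterm_impact(bundle, x, clim, events)
            row["longterm_mean_impact_pct"] = lt.longterm_mean_impact
            row["do_rate_actual"] = lt.do_rate_actual
            row["do_rate_no_hw"] = lt.do_rate_no_hw
        impact_rows.append(row)

    events_df = pd.DataFrame(ev_rows)
    impacts = pd.DataFrame(impact_rows)
    state["heatwave_impacts"] = impacts
    _write_csv(events_df, outdir / "heatwave_events.csv", index=False)
    _write_csv(impacts, outdir / "heatwave_impacts.csv", index=False)
    _write_csv(
        pd.concat(annual_days, ignore_index=True), outdir / "heatwave_days.csv",
        index=False,
    )
    manifest["stages"]["heatwave"] = {
        "status": "ok",
        "n_events": int(len(events_df)),
    }
    manifest["summary"]["mean_heatwave_days_per_year"] = float(
        impacts["heatwave_days_per_year"].mean()
    )
    manifest["summary"]["mean_influence_intensity_pct"] = float(
        impacts["mean_intensity_pct"].mean()
    )
    if "longterm_mean_impact_pct" in impacts:
        manifest["summary"]["mean_longterm_impact_pct"] = float(
            impacts["longterm_mean_impact_pct"].mean()
        )


def _stage_attribution(syn, cfg, state, outdir, manifest):
    models = []
    for lk in state["lakes"]:
        cs = state["climate_study"][lk.lake_id]
        p = state["predictions"][lk.lake_id]
        f = state["features"][lk.lake_id]
        ann = pd.DataFrame(
            {
                "t": cs["air_temperature"].groupby(cs.index.year).mean(),
                "wind": np.hypot(cs["wind_u"], cs["wind_v"])
                .groupby(cs.index.year)
                .mean(),
                "pressure": cs["pressure"].groupby(cs.index.year).mean(),
                "do": p["do"].groupby(p.index.year).mean(),
                "dosol": p["do_sol"].groupby(p.index.year).mean(),
                "fai": f["fai"].groupby(f.index.year).mean(),
            }
        )
        try:
            models.append(attribution.fit_path_model(ann, lake_id=lk.lake_id))
        except ValueError:
            continue
    if not models:
        raise RuntimeError("no lake had enough annual data for attribution")
    summary = attribution.mean_contributions(models)
    state["path_models"] = models

    _write_csv(attribution.models_frame(models), outdir / "path_models.csv", index=False)
    trends = state["trends"]
    do_rates = trends.query("variable == 'do'").set_index("lake_id")["slope_per_decade"]
    sol_rates = trends.query("variable == 'dosol'").set_index("lake_id")[
        "slope_per_decade"
    ]
    joined = pd.concat({"do": do_rates, "dosol": sol_rates}, axis=1).dropna()
    r, p = attribution.rate_correlation(joined["do"], joined["dosol"])
    blob = {
        "mean_contribution_pct": summary.mean_contribution_pct,
        "direction_counts": summary.direction_counts,
        "n_lakes": summary.n_lakes,
        "do_vs_dosol_rate_correlation": {"r": r, "p": p, "n": int(len(joined))},
    }
    with open(outdir / "attribution_summary.json", "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True)
    manifest["stages"]["attribution"] = {"status": "ok", "n_lakes": summary.n_lakes}
    manifest["summary"]["dosol_to_do_contribution_pct"] = summary.mean_contribution_pct[
        "dosol_to_do"
    ]
    manifest["summary"]["t_to_dosol_negative_count"] = summary.direction_counts[
        "t_to_dosol"
    ]["negative"]
    manifest["summary"]["do_vs_dosol_rate_r"] = r


def _stage_stress(syn, cfg, state, outdir, manifest):
    series = {
        lake_id: (p.index, p["do"].to_numpy())
        for lake_id, p in state["predictions"].items()
    }
    per_lake, counts = stress_projection.cohort_stress(
        series, threshold=cfg.stress_threshold
    )
    _write_csv(per_lake, outdir / "stress_per_lake.csv", index=False)
    _write_csv(counts, outdir / "stress_annual_counts.csv", index=False)
    manifest["stages"]["stress"] = {"status": "ok", "n_lakes": int(len(per_lake))}
    manifest["summary"]["n_ever_stressed_lakes"] = int(per_lake["ever_stressed"].sum())
    manifest["summary"]["stressed_count_trend_per_decade"] = counts.attrs[
        "count_trend_per_decade"
    ]


def _stage_project(syn, cfg, state, outdir, manifest):
    bundle = state["bundle"]
    future = pd.date_range(
        pd.Timestamp(syn.end_date) + pd.Timedelta(days=1),
        f"{cfg.projection_end_year}-12-01",
        freq="MS",
    )
    scen_rows = []
    ens_frames = []
    for lk in state["lakes"]:
        frozen = stress_projection.freeze_watercolour(
            state["features"][lk.lake_id], cfg.freeze_window_years
        )
        if frozen is None:
            continue
        static = _lake_static(lk)
        for scen, rate in sorted(cfg.scenarios.items()):
            members = {}
            for m in range(cfg.n_members):
                forcing = synthetic_data.make_climate(
                    lk,
                    dataclasses.replace(syn, seed=(syn.seed + 1000 * (m + 1)) & 0x7FFFFFFF),
                    dates=future,
                    warming_rate=rate,
                    heatwaves=False,
                )
                members[f"m{m}"] = forcing.drop(columns="heatwave_flag")
            res = stress_projection.project_do(bundle, members, frozen, static)
            scen_rows.append(
                {
                    "lake_id": lk.lake_id,
                    "scenario": scen,
                    "trend_mg_l_per_decade": res.ensemble_trend,
                    "final_do": float(res.ensemble["do_mean"].iloc[-12:].mean()),
                }
            )
            ens = res.ensemble.copy()
            ens["lake_id"] = lk.lake_id
            ens["scenario"] = scen
            ens_frames.append(ens.reset_index(names="date"))

    scen_df = pd.DataFrame(scen_rows)
    _write_csv(scen_df, outdir / "projection_trends.csv", index=False)
    ens_all = pd.concat(ens_frames, ignore_index=True)
    cohort = (
        ens_all.groupby(["scenario", "date"])["do_mean"].mean().reset_index()
    )
    _write_csv(cohort, outdir / "projection_cohort_mean.csv", index=False)
    manifest["stages"]["project"] = {
        "status": "ok",
        "n_lakes": int(scen_df["lake_id"].nunique()),
    }
    for scen, grp in scen_df.groupby("scenario"):
        manifest["summary"][f"projected_trend_{scen}_mg_l_per_decade"] = float(
            grp["trend_mg_l_per_decade"].mean()
        )
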