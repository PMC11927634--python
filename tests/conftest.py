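import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lakedo import do_model, synthetic_data
from lakedo.synthetic_data import SyntheticConfig


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A six-lake cohort at the default study conditions."""
    return SyntheticConfig(n_lakes=6, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """Lakes with study-period climate, trophic state, reflectance and truth."""
    lakes = synthetic_data.make_lakes(small_cfg)
    study = small_cfg.study_dates()
    data = {}
    for lk in lakes:
        climate = synthetic_data.make_climate(lk, small_cfg, dates=study)
        trophic = synthetic_data.make_trophic(lk, small_cfg, study)
        reflectance = synthetic_data.make_reflectance(lk, small_cfg, trophic)
        truth = synthetic_data.make_true_do(lk, climate, trophic, small_cfg)
        data[lk.lake_id] = {
            "lake": lk,
            "climate": climate,
            "trophic": trophic,
            "reflectance": reflectance,
            "truth": truth,
        }
    return data


def build_synthetic_matchups(cfg: SyntheticConfig, *, surveys_per_year=None,
                             g=None, noise=True) -> pd.DataFrame:
    """Full matchup table for a synthetic cohort (shared by several tests)."""
    from lakedo import water_optics

    lakes = synthetic_data.make_lakes(cfg)
    lake_meta = synthetic_data.lakes_frame(lakes)
    study = cfg.study_dates()
    obs_parts, clim_parts, refl_parts = [], [], []
    for lk in lakes:
        climate = synthetic_data.make_climate(lk, cfg, dates=study)
        trophic = synthetic_data.make_trophic(lk, cfg, study)
        refl = synthetic_data.make_reflectance(lk, cfg, trophic)
        truth = synthetic_data.make_true_do(lk, climate, trophic, cfg, g=g, noise=noise)
        obs = synthetic_data.make_observations(
            lk, truth, cfg, noise=noise, surveys_per_year=surveys_per_year
        )
        obs_parts.append(obs.assign(lake_id=lk.lake_id))
        c = climate.drop(columns="heatwave_flag").reset_index(names="date")
        c["time"] = c["date"] + pd.Timedelta(hours=12)
        clim_parts.append(c.drop(columns="date").assign(lake_id=lk.lake_id))
        f = pd.DataFrame(
            {
                "fai": water_optics.fai(refl["r_nir"], refl["r_red"], refl["r_swir"]),
                "hue_angle": water_optics.hue_angle(
                    refl["r_red"], refl["r_green"], refl["r_blue"]
                ).a_prime,
            },
            index=refl.index,
        ).reset_index(names="date")
        f["time"] = f["date"] + pd.Timedelta(hours=12)
        refl_parts.append(f.drop(columns="date").assign(lake_id=lk.lake_id))
    return do_model.build_matchups(
        pd.concat(obs_parts, ignore_index=True),
        pd.concat(clim_parts, ignore_index=True),
        pd.concat(refl_parts, ignore_index=True),
        lake_meta,
    )


@pytest.fixture(scope="session")
def fitted_bundle(small_cfg):
    """A small fitted RF bundle with its held-out table, for reuse."""
    matchups = build_synthetic_matchups(
        dataclasses.replace(small_cfg, n_lakes=12, surveys_per_year=25.0)
    )
    train, test = do_model.train_test_split_rows(matchups, seed=3)
    bundle = do_model.fit_model(
        train, grid={"n_estimators": [60], "max_depth": [15], "min_samples_leaf": [2]},
        seed=3,
    )
    return bundle, train, test
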