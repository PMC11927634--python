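"""Determinism, construction invariants and recoverability of the generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lakedo import synthetic_data as sd
from lakedo import trend_analysis, water_optics
from lakedo.synthetic_data import AlignmentError, ConfigError, SyntheticConfig


class TestConfig:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_lakes=0).validate()

    def test_backwards_dates_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(start_date="2023-01-01", end_date="2003-01-01").validate()

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(noise_sd_do=-1.0).validate()


class TestMakeLakes:
    def test_seed_determinism(self):
        cfg = SyntheticConfig(n_lakes=100, seed=1)
        a = sd.lakes_frame(sd.make_lakes(cfg))
        b = sd.lakes_frame(sd.make_lakes(cfg))
        pd.testing.assert_frame_equal(a, b)

    def test_latitude_bands_all_populated(self):
        lakes = sd.lakes_frame(sd.make_lakes(SyntheticConfig(n_lakes=500, seed=7)))
        lat = lakes["latitude"]
        assert ((lat >= 30) & (lat <= 65)).any()      # NH temperate
        assert ((lat <= -30) & (lat >= -55)).any()    # SH temperate
        assert (lat.abs() < 30).any()                 # tropics

    def test_physical_ranges(self):
        lakes = sd.lakes_frame(sd.make_lakes(SyntheticConfig(n_lakes=300, seed=2)))
        assert lakes["area"].min() >= 10.0
        assert lakes["elevation"].between(0, 5000).all()
        assert lakes["latitude"].between(-90, 90).all()
        assert lakes["longitude"].between(-180, 180).all()


class TestMakeClimate:
    @pytest.fixture(scope="class")
    def cfg(self):
        return SyntheticConfig(n_lakes=4, seed=3)

    def test_pure_seasonal_limit_is_periodic(self, cfg):
        lake = sd.make_lakes(cfg)[0]
        quiet = dataclasses.replace(cfg, warming_rate=0.0, heatwave_rate=0.0)
        clim = sd.make_climate(lake, quiet, noise=False, heatwaves=False)
        t = clim["air_temperature"].to_numpy()
        # 4 x 365.25 = 1461 days is an exact period of the seasonal cycle
        np.testing.assert_allclose(t[:-1461], t[1461:], atol=1e-9)

    def test_warming_rate_recovered_by_regression(self, cfg):
        lake = sd.make_lakes(cfg)[1]
        clim = sd.make_climate(
            lake, dataclasses.replace(cfg, heatwave_rate=0.0), lake_index=1
        )
        ann = clim["air_temperature"].groupby(clim.index.year).mean()
        slope = np.polyfit(ann.index, ann.to_numpy(), 1)[0] * 10.0
        assert slope == pytest.approx(cfg.warming_rate, abs=0.05)

    def test_hemisphere_cycles_antiphased(self, cfg):
        north = sd.LakeMeta("L00000", 40.0, 0.0, 100.0, 50.0)
        south = sd.LakeMeta("L00001", -40.0, 0.0, 100.0, 50.0)
        quiet = dataclasses.replace(cfg, warming_rate=0.0)
        dates = pd.date_range("2003-01-01", "2005-12-31", freq="D")
        tn = sd.make_climate(north, quiet, dates=dates, noise=False, heatwaves=False)
        ts = sd.make_climate(south, quiet, dates=dates, noise=False, heatwaves=False)
        peak_n = tn["air_temperature"].idxmax().month
        peak_s = ts["air_temperature"].idxmax().month
        assert abs(peak_n - peak_s) in (5, 6, 7)

    def test_pressure_decreases_with_elevation(self, cfg):
        low = sd.LakeMeta("L00000", 10.0, 0.0, 0.0, 50.0)
        high = sd.LakeMeta("L00001", 10.0, 0.0, 4000.0, 50.0)
        p_low = sd.make_climate(low, cfg, noise=False)["pressure"].iloc[0]
        p_high = sd.make_climate(high, cfg, noise=False)["pressure"].iloc[0]
        assert p_high < p_low < 1.01

    def test_injected_heatwave_blocks_long_and_flagged(self, cfg):
        lake = sd.make_lakes(cfg)[2]
        hot = dataclasses.replace(cfg, heatwave_rate=3.0)
        clim = sd.make_climate(lake, hot, lake_index=2)
        flags = clim["heatwave_flag"].to_numpy()
        assert flags.any()
        # no injection inside the baseline period
        assert not clim.loc[:"1999-12-31", "heatwave_flag"].any()
        # every injected run lasts at least 5 days (runs may merge)
        padded = np.concatenate([[False], flags, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        assert ((ends - starts) >= 5).all()

    def test_gap_free_daily(self, cfg):
        lake = sd.make_lakes(cfg)[0]
        clim = sd.make_climate(lake, cfg)
        assert (np.diff(clim.index.values).astype("timedelta64[D]") == 1).all()


class TestReflectance:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = SyntheticConfig(n_lakes=2, seed=9)
        lake = sd.make_lakes(cfg)[0]
        dates = cfg.study_dates()
        return cfg, lake, dates

    def test_bands_bounded(self, setup):
        cfg, lake, dates = setup
        trophic = sd.make_trophic(lake, cfg, dates)
        refl = sd.make_reflectance(lake, cfg, trophic)
        assert (refl.to_numpy() >= 0).all() and (refl.to_numpy() <= 1).all()

    def test_fai_tracks_trophic_trend(self, setup):
        cfg, lake, dates = setup
        trend_cfg = dataclasses.replace(cfg, trophic_trend=0.3)
        trophic = sd.make_trophic(lake, trend_cfg, dates)
        refl = sd.make_reflectance(lake, trend_cfg, trophic)
        f = water_optics.fai(refl["r_nir"], refl["r_red"], refl["r_swir"])
        first = f[refl.index < "2008-01-01"].mean()
        last = f[refl.index >= "2019-01-01"].mean()
        assert last > first

    def test_constant_trophic_gives_flat_fai(self, setup):
        cfg, lake, dates = setup
        trophic = pd.Series(0.5, index=dates)
        refl = sd.make_reflectance(lake, cfg, trophic)
        f = pd.Series(
            water_optics.fai(refl["r_nir"], refl["r_red"], refl["r_swir"]),
            index=refl.index,
        )
        ann = f.groupby(refl.index.year).mean()
        slope = trend_analysis.theil_sen(ann.index, ann.to_numpy())
        assert abs(slope) < 5e-4  # FAI units/decade, noise floor

    def test_sampling_is_sparse(self, setup):
        cfg, lake, dates = setup
        trophic = sd.make_trophic(lake, cfg, dates)
        refl = sd.make_reflectance(lake, cfg, trophic)
        per_year = len(refl) / (len(dates) / 365.25)
        assert 15 < per_year < 45  # around the ~28.5 clear obs/year target

    def test_noiseless_fai_monotone_in_trophic(self, setup):
        cfg, lake, dates = setup
        trophic = pd.Series(np.linspace(0.05, 2.0, len(dates)), index=dates)
        refl = sd.make_reflectance(lake, cfg, trophic, noise=False, sample_all=True)
        f = water_optics.fai(refl["r_nir"], refl["r_red"], refl["r_swir"])
        assert (np.diff(f) > 0).all()


class TestTrueDO:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = SyntheticConfig(n_lakes=3, seed=13)
        lakes = sd.make_lakes(cfg)
        dates = cfg.study_dates()
        return cfg, lakes, dates

    def test_pure_saturation_limit(self, setup):
        cfg, lakes, dates = setup
        clim = sd.make_climate(lakes[0], cfg, dates=dates)
        trophic = sd.make_trophic(lakes[0], cfg, dates)
        truth = sd.make_true_do(lakes[0], clim, trophic, cfg, g=0.0, noise=False)
        np.testing.assert_array_equal(truth["true_do"], truth["do_sol"])

    def test_monotone_in_trophic_at_fixed_climate(self, setup):
        cfg, lakes, dates = setup
        d = dates[:500]
        clim = sd.make_climate(lakes[0], cfg, dates=d, noise=False, heatwaves=False)
        clim["air_temperature"] = 15.0
        clim["solar"] = 200.0
        low = sd.make_true_do(lakes[0], clim, pd.Series(0.1, index=d), cfg, noise=False)
        high = sd.make_true_do(lakes[0], clim, pd.Series(1.5, index=d), cfg, noise=False)
        assert (high["true_do"] > low["true_do"]).all()

    def test_warming_only_cohort_deoxygenates(self, setup):
        cfg, lakes, dates = setup
        warm = dataclasses.replace(cfg, warming_rate=0.5, heatwave_rate=0.0)
        for i, lake in enumerate(lakes):
            clim = sd.make_climate(lake, warm, dates=dates, lake_index=i)
            trophic = sd.make_trophic(lake, warm, dates, lake_index=i)
            truth = sd.make_true_do(lake, clim, trophic, warm, g=0.0, lake_index=i)
            ann = truth["true_do"].groupby(truth.index.year).mean()
            assert np.polyfit(ann.index, ann.to_numpy(), 1)[0] < 0

    def test_misaligned_series_rejected(self, setup):
        cfg, lakes, dates = setup
        clim = sd.make_climate(lakes[0], cfg, dates=dates[:100])
        trophic = sd.make_trophic(lakes[0], cfg, dates[50:150])
        with pytest.raises(AlignmentError):
            sd.make_true_do(lakes[0], clim, trophic, cfg)

    def test_supersaturation_bounded_by_c1(self, setup):
        cfg, lakes, dates = setup
        clim = sd.make_climate(lakes[1], cfg, dates=dates, lake_index=1)
        trophic = sd.make_trophic(lakes[1], cfg, dates, lake_index=1)
        truth = sd.make_true_do(lakes[1], clim, trophic, cfg, noise=False, lake_index=1)
        sp = 100.0 * (truth["true_do"] - truth["do_sol"]) / truth["do_sol"]
        assert sp.max() <= 100.0 * cfg.supersat_c1 + 1e-9
        assert sp.min() >= 0.0


class TestObservations:
    def test_noiseless_observations_equal_truth(self):
        cfg = SyntheticConfig(n_lakes=1, seed=4)
        lake = sd.make_lakes(cfg)[0]
        dates = cfg.study_dates()
        clim = sd.make_climate(lake, cfg, dates=dates)
        trophic = sd.make_trophic(lake, cfg, dates)
        truth = sd.make_true_do(lake, clim, trophic, cfg)
        obs = sd.make_observations(lake, truth, cfg, noise=False)
        merged = obs.set_index("date").join(truth["true_do"])
        np.testing.assert_allclose(merged["do_obs"], merged["true_do"])

    def test_observation_count_scales_with_survey_frequency(self):
        cfg = SyntheticConfig(n_lakes=1, seed=4)
        lake = sd.make_lakes(cfg)[0]
        dates = cfg.study_dates()
        clim = sd.make_climate(lake, cfg, dates=dates)
        trophic = sd.make_trophic(lake, cfg, dates)
        truth = sd.make_true_do(lake, clim, trophic, cfg)
        n12 = len(sd.make_observations(lake, truth, cfg, surveys_per_year=12))
        n48 = len(sd.make_observations(lake, truth, cfg, surveys_per_year=48))
        assert n48 / n12 == pytest.approx(4.0, rel=0.25)


class TestTrendCohort:
    def test_imposed_trend_recovered_per_lake(self):
        df = sd.make_trend_series(8, -0.3, noise_sd=0.1, seed=5)
        for _, grp in df.groupby("lake_id"):
            ann = trend_analysis.summer_annual_median(
                grp["date"], grp["do"].to_numpy(), grp["hemisphere"].iloc[0]
            )
            slope = trend_analysis.theil_sen(ann.years, ann.values)
            assert slope == pytest.approx(-0.3, abs=0.1)


class TestPathCohort:
    def test_population_weights_match_construction(self):
        frames = sd.make_path_cohort(300, noise_scale=0.0, seed=6)
        big = pd.concat(frames, ignore_index=True)
        # with noise off, dosol is an exact linear function of the drivers
        resid = big["dosol"] - (-0.85 * big["t"] + 0.25 * big["wind"] + 0.05 * big["pressure"])
        assert resid.abs().max() < 1e-4
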