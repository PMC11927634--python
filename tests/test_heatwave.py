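"""Day-specific climatology, event detection and counterfactual impacts."""

import numpy as np
import pandas as pd
import pytest

from lakedo import heatwave as hw
from lakedo import oxygen_physics as ox
from lakedo import synthetic_data
from lakedo.do_model import SolubilityPredictor
from lakedo.synthetic_data import SyntheticConfig


def brute_force_events(temps, thresholds, min_duration=5):
    """Run-length-encoding oracle: maximal exceedance runs >= min_duration."""
    events = []
    run_start = None
    for i, (t, thr) in enumerate(zip(temps, thresholds)):
        if t > thr:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_duration:
                events.append((run_start, i - 1))
            run_start = None
    if run_start is not None and len(temps) - run_start >= min_duration:
        events.append((run_start, len(temps) - 1))
    return events


@pytest.fixture(scope="module")
def baseline_clim():
    dates = pd.date_range("1970-01-01", "1999-12-31", freq="D")
    rng = np.random.default_rng(4)
    doy = dates.dayofyear.to_numpy().astype(float)
    temps = 12.0 + 8.0 * np.cos(2 * np.pi * (doy - 200) / 365.25) + rng.normal(0, 2, len(dates))
    return dates, temps, hw.day_climatology(dates, temps)


class TestDayClimatology:
    def test_leap_day_maps_onto_slot_59(self):
        days = hw.doy_365(pd.DatetimeIndex(["2004-02-28", "2004-02-29", "2004-03-01"]))
        assert list(days) == [59, 59, 60]
        # and Dec 31 of a leap year still lands on slot 365
        assert hw.doy_365(pd.DatetimeIndex(["2004-12-31"]))[0] == 365

    def test_constant_baseline_gives_constant_threshold(self):
        dates = pd.date_range("1990-01-01", "1994-12-31", freq="D")
        with pytest.warns(UserWarning):
            clim = hw.day_climatology(dates, np.full(len(dates), 10.0))
        assert np.allclose(clim.threshold, 10.0)
        assert np.allclose(clim.mean_temp, 10.0)

    def test_percentile_matches_sort_based_oracle(self):
        # each calendar day sees exactly the values 1..30 across 30 years
        dates = pd.date_range("1970-01-01", "1999-12-31", freq="D")
        year_rank = (dates.year.to_numpy() - 1969).astype(float)
        clim = hw.day_climatology(dates, year_rank)
        expected = np.percentile(np.arange(1, 31), 90)  # linear interpolation rule
        not59 = np.arange(365) != 58
        assert np.allclose(clim.threshold[not59], expected)
        # slot 59 additionally pools the leap-year Feb 29 samples
        pooled = year_rank[hw.doy_365(dates) == 59]
        assert clim.threshold[58] == pytest.approx(np.percentile(pooled, 90))

    def test_threshold_at_least_mean(self, baseline_clim):
        _, _, clim = baseline_clim
        assert np.all(clim.threshold >= clim.mean_temp)

    def test_too_short_baseline_rejected(self):
        dates = pd.date_range("1999-01-01", "1999-12-31", freq="D")
        with pytest.raises(ValueError):
            hw.day_climatology(dates, np.zeros(len(dates)))


class TestDetectEvents:
    def _study(self, clim, exceed_days, amp=3.0):
        dates = pd.date_range("2003-01-01", "2003-12-31", freq="D")
        doy = hw.doy_365(dates) - 1
        temps = clim.mean_temp[doy] - 1.0  # below threshold everywhere
        temps[100 : 100 + exceed_days] = clim.threshold[doy[100 : 100 + exceed_days]] + amp
        return dates, temps

    def test_four_day_spike_is_not_an_event(self, baseline_clim):
        _, _, clim = baseline_clim
        dates, temps = self._study(clim, 4)
        assert hw.detect_events(dates, temps, clim) == []

    def test_five_day_run_is_one_event(self, baseline_clim):
        _, _, clim = baseline_clim
        dates, temps = self._study(clim, 5)
        events = hw.detect_events(dates, temps, clim)
        assert len(events) == 1 and events[0].duration == 5
        assert events[0].exceedance == pytest.approx(3.0)

    def test_events_may_cross_year_boundary(self, baseline_clim):
        _, _, clim = baseline_clim
        dates = pd.date_range("2003-12-25", "2004-01-10", freq="D")
        doy = hw.doy_365(dates) - 1
        temps = clim.threshold[doy] + 1.0
        events = hw.detect_events(dates, temps, clim)
        assert len(events) == 1 and events[0].duration == len(dates)

    def test_gapped_series_rejected(self, baseline_clim):
        _, _, clim = baseline_clim
        dates = pd.DatetimeIndex(["2003-01-01", "2003-01-03"])
        with pytest.raises(ValueError, match="gap"):
            hw.detect_events(dates, np.array([5.0, 5.0]), clim)

    def test_matches_rle_oracle_on_random_series(self, baseline_clim):
        _, _, clim = baseline_clim
        rng = np.random.default_rng(23)
        dates = pd.date_range("2003-01-01", "2006-12-31", freq="D")
        doy = hw.doy_365(dates) - 1
        for _ in range(100):
            temps = clim.mean_temp[doy] + rng.normal(0, 4.0, len(dates))
            events = hw.detect_events(dates, temps, clim)
            expected = brute_force_events(temps, clim.threshold[doy])
            got = [
                ((e.start - dates[0]).days, (e.end - dates[0]).days) for e in events
            ]
            assert got == expected

    def test_every_injected_block_above_threshold_is_detected(self):
        cfg = SyntheticConfig(n_lakes=3, seed=21, heatwave_rate=3.0, heatwave_amp=6.0)
        for i, lake in enumerate(synthetic_data.make_lakes(cfg)):
            full = synthetic_data.make_climate(lake, cfg)
            base = full.loc["1970":"1999"]
            clim = hw.day_climatology(base.index, base["air_temperature"].to_numpy())
            study = full.loc["2003":]
            temps = study["air_temperature"].to_numpy()
            thr = clim.threshold[hw.doy_365(study.index) - 1]
            events = hw.detect_events(study.index, temps, clim)
            covered = hw.heatwave_day_mask(study.index, events)
            hot_injected = study["heatwave_flag"].to_numpy() & (temps > thr)
            for s, e in brute_force_events(
                hot_injected.astype(float), np.full(len(temps), 0.5)
            ):
                assert covered[s : e + 1].all()

    def test_no_event_day_sits_below_threshold(self, baseline_clim):
        _, _, clim = baseline_clim
        rng = np.random.default_rng(31)
        dates = pd.date_range("2003-01-01", "2004-12-31", freq="D")
        doy = hw.doy_365(dates) - 1
        temps = clim.mean_temp[doy] + rng.normal(0, 4.0, len(dates))
        events = hw.detect_events(dates, temps, clim)
        mask = hw.heatwave_day_mask(dates, events)
        assert np.all(temps[mask] > clim.threshold[doy[mask]])


class TestDurationStats:
    def test_no_events(self):
        out = hw.duration_stats([], range(2003, 2008))
        assert (out["heatwave_days"] == 0).all()
        assert out.attrs["trend_days_per_year"] == pytest.approx(0.0)

    def test_one_weeklong_event_per_year_is_flat(self):
        events = [
            hw.HeatwaveEvent(
                start=pd.Timestamp(f"{y}-07-01"),
                end=pd.Timestamp(f"{y}-07-07"),
                duration=7,
                exceedance=1.0,
            )
            for y in range(2003, 2010)
        ]
        out = hw.duration_stats(events, range(2003, 2010))
        assert (out["heatwave_days"] == 7).all()
        assert out.attrs["trend_days_per_year"] == pytest.approx(0.0)

    def test_recovers_injected_linear_increase(self):
        events = []
        for k, y in enumerate(range(2003, 2024)):
            for j in range(1 + k):  # one extra 5-day event each year
                start = pd.Timestamp(f"{y}-01-01") + pd.Timedelta(days=10 * j)
                events.append(
                    hw.HeatwaveEvent(start, start + pd.Timedelta(days=4), 5, 1.0)
                )
        out = hw.duration_stats(events, range(2003, 2024))
        assert out.attrs["trend_days_per_year"] == pytest.approx(5.0, rel=0.2)


class TestCounterfactualImpacts:
    @pytest.fixture()
    def flat_clim(self):
        dates = pd.date_range("1970-01-01", "1999-12-31", freq="D")
        return hw.day_climatology(dates, np.full(len(dates), 20.0))

    def _features(self, temps, dates):
        return pd.DataFrame(
            {"air_temperature": temps, "pressure": np.ones(len(dates))}, index=dates
        )

    def test_identity_counterfactual_is_zero(self, flat_clim):
        dates = pd.date_range("2003-06-01", periods=30, freq="D")
        feats = self._features(np.full(30, 20.0), dates)
        ev = [hw.HeatwaveEvent(dates[5], dates[12], 8, 0.0)]
        rep = hw.influence_intensity(SolubilityPredictor(), feats, flat_clim, ev)
        assert rep.mean_intensity == pytest.approx(0.0, abs=1e-12)
        assert rep.max_intensity == pytest.approx(0.0, abs=1e-12)

    def test_solubility_oracle_matches_analytic_ratio(self, flat_clim):
        dates = pd.date_range("2003-06-01", periods=30, freq="D")
        temps = np.full(30, 20.0)
        temps[10:17] = 25.0  # +5 degC heatwave at a 20 degC baseline
        feats = self._features(temps, dates)
        ev = [hw.HeatwaveEvent(dates[10], dates[16], 7, 5.0)]
        rep = hw.influence_intensity(SolubilityPredictor(), feats, flat_clim, ev)
        expected = 100.0 * (ox.solubility(25.0) - ox.solubility(20.0)) / ox.solubility(20.0)
        assert rep.mean_intensity == pytest.approx(expected, abs=1e-6)
        assert rep.max_intensity == pytest.approx(expected, abs=1e-6)
        assert expected < 0

    def test_max_magnitude_bounds_mean(self, flat_clim):
        rng = np.random.default_rng(12)
        dates = pd.date_range("2003-06-01", periods=60, freq="D")
        temps = 20.0 + rng.uniform(0, 6, 60)
        feats = self._features(temps, dates)
        ev = [
            hw.HeatwaveEvent(dates[5], dates[12], 8, 1.0),
            hw.HeatwaveEvent(dates[30], dates[36], 7, 1.0),
        ]
        rep = hw.influence_intensity(SolubilityPredictor(), feats, flat_clim, ev)
        assert abs(rep.max_intensity) >= abs(rep.mean_intensity)

    def test_longterm_impact_zero_without_events(self, flat_clim):
        dates = pd.date_range("2003-01-01", "2006-12-31", freq="D")
        feats = self._features(np.full(len(dates), 21.0), dates)
        rep = hw.longterm_impact(SolubilityPredictor(), feats, flat_clim, [])
        assert rep.longterm_mean_impact == pytest.approx(0.0)
        assert rep.do_rate_actual == pytest.approx(rep.do_rate_no_hw)

    def test_longterm_impact_negative_under_heatwaves(self, flat_clim):
        dates = pd.date_range("2003-01-01", "2006-12-31", freq="D")
        temps = np.full(len(dates), 20.0)
        ev = []
        for y in range(2003, 2007):
            s = pd.Timestamp(f"{y}-07-01")
            e = s + pd.Timedelta(days=9)
            sel = (dates >= s) & (dates <= e)
            temps[sel] += 5.0
            ev.append(hw.HeatwaveEvent(s, e, 10, 5.0))
        feats = self._features(temps, dates)
        rep = hw.longterm_impact(SolubilityPredictor(), feats, flat_clim, ev)
        assert rep.longterm_mean_impact < 0

    def test_impact_magnitude_grows_with_amplitude(self, flat_clim):
        dates = pd.date_range("2003-06-01", periods=40, freq="D")
        ev = [hw.HeatwaveEvent(dates[10], dates[19], 10, 0.0)]
        impacts = []
        for amp in (2.0, 4.0, 6.0):
            temps = np.full(40, 20.0)
            temps[10:20] += amp
            rep = hw.influence_intensity(
                SolubilityPredictor(), self._features(temps, dates), flat_clim, ev
            )
            impacts.append(rep.mean_intensity)
        assert impacts[0] > impacts[1] > impacts[2]  # increasingly negative
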