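"""Synthetic lake cohorts with known ground truth.

Every downstream stage — water-colour indices, the DO regressor, trend
analysis, heatwave attribution, stress projection — is exercised on
synthetic lakes whose generating mechanisms are known exactly, so that
recovery can be asserted rather than eyeballed.  The generator emulates:

* a global cohort of lakes (>= 10 km^2) spanning both hemispheres and
  the tropics, with elevations up to 5000 m;
* daily climate forcing per lake: a hemisphere-phased seasonal
  temperature cycle plus a linear warming trend, AR(1) weather noise
  (coefficient 0.7 for realistic persistence), and injectable heatwave
  blocks of >= 5 consecutive days at a configurable amplitude; pressure
  follows the barometric formula; solar/thermal radiation, precipitation
  and wind components carry plausible seasonality and noise;
* a latent trophic state per lake (slowly trending, seasonally blooming)
  that drives 5-band reflectance such that the floating algae index
  computed downstream increases with the latent state; sampling is
  sparse and irregular (~28.5 clear observations per year);
* "true" DO as solubility modulated by a bounded
  photosynthesis/trophic factor ``g`` plus Gaussian noise:
  ``DO(t) = DOsol(T, P) * (1 + g(trophic, solar)) + eps``, with the
  default ``g = c1 * tanh(c2 * trophic) * solar/solar_max`` capping
  supersaturation at c1 = 15%;
* sparse, noisy in situ survey observations for matchup training.

All draws derive from ``SyntheticConfig.seed`` via per-lake,
per-component substreams: identical configs give bit-identical tables.
Heatwave blocks are injected only after the climatological baseline
period, so the baseline percentile climatology stays uncontaminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import oxygen_physics

__all__ = [
    "SyntheticConfig",
    "LakeMeta",
    "ConfigError",
    "AlignmentError",
    "make_lakes",
    "lakes_frame",
    "make_climate",
    "make_trophic",
    "make_reflectance",
    "make_true_do",
    "make_observations",
    "make_trend_series",
    "default_g",
]

DAYS_PER_YEAR = 365.25
SOLUBILITY_T_CLIP = (-2.0, 45.0)  # air temp clipped to the solubility domain


class ConfigError(ValueError):
    """Invalid synthetic-generator configuration."""


class AlignmentError(ValueError):
    """Input series are not aligned on the same dates."""


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the study design: a 2003–2023 analysis period, a
    1970–1999 percentile baseline, and contemporary warming of 0.3 degC
    per decade.  ``noise_sd_do`` is process noise on true DO;
    ``obs_noise_sd`` (0.3 mg/L) is the in situ observation error of an
    optical DO meter.
    """

    n_lakes: int = 200
    start_date: str = "2003-01-01"
    end_date: str = "2023-12-31"
    climatology_start: str = "1970-01-01"
    climatology_end: str = "1999-12-31"
    warming_rate: float = 0.3          # degC per decade
    heatwave_rate: float = 2.0         # expected injected events per year
    heatwave_amp: float = 5.0          # degC above the seasonal expectation
    trophic_trend: float = 0.1         # latent trophic units per decade
    noise_sd_do: float = 0.3           # mg/L
    obs_noise_sd: float = 0.3          # mg/L
    weather_noise_sd: float = 2.0      # degC, stationary AR(1) sd
    ar_coef: float = 0.7
    surveys_per_year: float = 12.0
    reflectance_per_year: float = 28.5
    supersat_c1: float = 0.15          # max supersaturation fraction
    supersat_c2: float = 1.0           # trophic sensitivity of g
    seed: int = 0

    def validate(self) -> None:
        if self.n_lakes < 1:
            raise ConfigError("n_lakes must be >= 1")
        if pd.Timestamp(self.end_date) <= pd.Timestamp(self.start_date):
            raise ConfigError("end_date must be after start_date")
        if pd.Timestamp(self.climatology_end) <= pd.Timestamp(self.climatology_start):
            raise ConfigError("climatology_end must be after climatology_start")
        for name in ("noise_sd_do", "obs_noise_sd", "weather_noise_sd",
                     "heatwave_rate", "heatwave_amp", "surveys_per_year",
                     "reflectance_per_year"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 <= self.ar_coef < 1):
            raise ConfigError("ar_coef must be in [0, 1)")

    def study_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, self.end_date, freq="D")

    def full_dates(self) -> pd.DatetimeIndex:
        """Baseline-through-study daily axis (for climatology building)."""
        start = min(pd.Timestamp(self.climatology_start), pd.Timestamp(self.start_date))
        return pd.date_range(start, self.end_date, freq="D")


@dataclass(frozen=True)
class LakeMeta:
    """Static attributes of one lake."""

    lake_id: str
    latitude: float     # degrees, [-90, 90]
    longitude: float    # degrees, [-180, 180)
    elevation: float    # metres
    area: float         # km^2, >= 10

    @property
    def hemisphere(self) -> str:
        return "N" if self.latitude >= 0 else "S"


def _rng(cfg: SyntheticConfig, *stream) -> np.random.Generator:
    # Independent, reproducible substream per (lake, component).
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, *stream])


# Latitude bands cycled over the cohort so every band is populated for
# any n_lakes >= 3: NH temperate, SH temperate, tropics.
_LAT_BANDS = ((30.0, 65.0), (-55.0, -30.0), (-29.0, 29.0))


def make_lakes(cfg: SyntheticConfig) -> list[LakeMeta]:
    """Generate the lake cohort (ids, coordinates, elevation, area)."""
    cfg.validate()
    rng = _rng(cfg, 0)
    lakes = []
    for i in range(cfg.n_lakes):
        lo, hi = _LAT_BANDS[i % len(_LAT_BANDS)]
        lat = float(rng.uniform(lo, hi))
        lon = float(rng.uniform(-180.0, 180.0))
        elev = float(np.clip(rng.gamma(1.5, 400.0), 0.0, 5000.0))
        area = float(10.0 + rng.lognormal(3.0, 1.2))
        lakes.append(
            LakeMeta(
                lake_id=f"L{i:05d}",
                latitude=lat,
                longitude=lon,
                elevation=elev,
                area=area,
            )
        )
    return lakes


def lakes_frame(lakes) -> pd.DataFrame:
    return pd.DataFrame([asdict(lk) for lk in lakes]).set_index("lake_id")


def _ar1(rng, n, sd, rho):
    if sd == 0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    from scipy.signal import lfilter

    out = lfilter([1.0], [1.0, -rho], eps)
    # spin-up: start from a stationary draw
    out[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -rho], np.concatenate([[out[0]], eps[1:]]))


def _seasonal_phase(latitude: float, doy: np.ndarray) -> np.ndarray:
    # Temperature peaks near day 200 in the NH and near day 20 in the SH.
    peak = 200.0 if latitude >= 0 else 20.0
    return np.cos(2.0 * np.pi * (doy - peak) / DAYS_PER_YEAR)


def make_climate(
    lake: LakeMeta,
    cfg: SyntheticConfig,
    *,
    dates: pd.DatetimeIndex | None = None,
    lake_index: int | None = None,
    warming_rate: float | None = None,
    noise: bool = True,
    heatwaves: bool = True,
) -> pd.DataFrame:
    """Daily climate forcing for one lake over ``dates`` (default: full span).

    Returns a date-indexed frame with columns ``air_temperature`` (degC),
    ``pressure`` (atm), ``solar``/``thermal`` (W/m^2), ``precip`` (mm),
    ``wind_u``/``wind_v`` (m/s) and the generator's ``heatwave_flag``.
    """
    cfg.validate()
    if dates is None:
        dates = cfg.full_dates()
    idx = int(lake.lake_id[1:]) if lake_index is None else lake_index
    rng = _rng(cfg, 1, idx)
    wr = cfg.warming_rate if warming_rate is None else warming_rate
    n = len(dates)
    doy = dates.dayofyear.to_numpy().astype(float)
    years = (dates - dates[0]).days.to_numpy() / DAYS_PER_YEAR

    base = 27.0 - 0.38 * abs(lake.latitude) - 6.5 * lake.elevation / 1000.0
    amp = 2.0 + 0.25 * abs(lake.latitude)
    temp = base + amp * _seasonal_phase(lake.latitude, doy) + wr * years / 10.0
    if noise:
        temp = temp + _ar1(rng, n, cfg.weather_noise_sd, cfg.ar_coef)

    hw_flag = np.zeros(n, dtype=bool)
    if heatwaves and cfg.heatwave_rate > 0 and cfg.heatwave_amp > 0:
        # inject only after the baseline period, keeping climatology clean
        clim_end = pd.Timestamp(cfg.climatology_end)
        eligible = np.flatnonzero(dates > clim_end)
        if eligible.size:
            n_years_study = max(1.0, eligible.size / DAYS_PER_YEAR)
            n_events = rng.poisson(cfg.heatwave_rate * n_years_study)
            for _ in range(n_events):
                start = int(rng.choice(eligible))
                dur = 5 + int(rng.poisson(3.0))
                stop = min(start + dur, n)
                temp[start:stop] += cfg.heatwave_amp
                hw_flag[start:stop] = True

    pressure = oxygen_physics.pressure_from_elevation(lake.elevation) * np.ones(n)
    if noise:
        pressure = pressure + _ar1(rng, n, 0.004, cfg.ar_coef)

    solar_seas = 180.0 + 120.0 * _seasonal_phase(lake.latitude, doy)
    solar = np.maximum(solar_seas, 5.0)
    thermal = 300.0 + 4.0 * temp
    precip = np.zeros(n)
    wind_u = 2.0 * np.ones(n)
    wind_v = 0.5 * np.ones(n)
    if noise:
        cloud = np.clip(rng.beta(5.0, 1.5, size=n), 0.05, 1.0)
        solar = solar * cloud
        thermal = thermal + rng.normal(0.0, 10.0, size=n)
        wet = rng.random(n) < 0.35
        precip = np.where(wet, rng.gamma(0.8, 4.0, size=n), 0.0)
        wind_u = wind_u + _ar1(rng, n, 1.5, cfg.ar_coef)
        wind_v = wind_v + _ar1(rng, n, 1.5, cfg.ar_coef)

    return pd.DataFrame(
        {
            "air_temperature": temp,
            "pressure": pressure,
            "solar": solar,
            "thermal": thermal,
            "precip": precip,
            "wind_u": wind_u,
            "wind_v": wind_v,
            "heatwave_flag": hw_flag,
        },
        index=dates,
    )


def make_trophic(
    lake: LakeMeta,
    cfg: SyntheticConfig,
    dates: pd.DatetimeIndex,
    *,
    lake_index: int | None = None,
    noise: bool = True,
    trend: float | None = None,
) -> pd.Series:
    """Latent trophic state (dimensionless, >= 0) on a daily axis.

    A per-lake baseline with a summer bloom season, a slow linear trend
    (``cfg.trophic_trend`` per decade) and AR(1) wobble.
    """
    idx = int(lake.lake_id[1:]) if lake_index is None else lake_index
    rng = _rng(cfg, 2, idx)
    tr = cfg.trophic_trend if trend is None else trend
    n = len(dates)
    doy = dates.dayofyear.to_numpy().astype(float)
    decades = (dates - dates[0]).days.to_numpy() / DAYS_PER_YEAR / 10.0

    base = float(rng.lognormal(-0.7, 0.5))  # median ~0.5
    bloom = 0.5 * base * np.maximum(_seasonal_phase(lake.latitude, doy), 0.0)
    latent = base + bloom + tr * decades
    if noise:
        latent = latent + _ar1(rng, n, 0.1 * base, cfg.ar_coef)
    return pd.Series(np.clip(latent, 0.01, None), index=dates, name="latent_trophic")


# Reflectance construction constants: band baselines and the FAI scale
# that converts latent trophic units into reflectance units.
_R_RED0, _R_SWIR0, _R_GREEN0, _R_BLUE0 = 0.025, 0.012, 0.045, 0.035
FAI_PER_TROPHIC = 0.02
_NIR_BASELINE_SLOPE = (859.0 - 645.0) / (1240.0 - 645.0)


def make_reflectance(
    lake: LakeMeta,
    cfg: SyntheticConfig,
    trophic: pd.Series,
    *,
    lake_index: int | None = None,
    noise: bool = True,
    sample_all: bool = False,
) -> pd.DataFrame:
    """Sparse, irregular 5-band water-leaving reflectance samples.

    Constructed so that the NIR band sits above the red–SWIR baseline by
    ``FAI_PER_TROPHIC * latent_trophic``: the floating algae index
    computed downstream recovers the latent state (up to noise).  Green
    rises and blue falls with the trophic state, moving the hue angle.
    All bands are clipped to [0, 1].
    """
    idx = int(lake.lake_id[1:]) if lake_index is None else lake_index
    rng = _rng(cfg, 3, idx)
    dates = trophic.index
    if sample_all:
        keep = np.ones(len(dates), dtype=bool)
    else:
        keep = rng.random(len(dates)) < cfg.reflectance_per_year / DAYS_PER_YEAR
    dates = dates[keep]
    lat = trophic.to_numpy()[keep]
    n = len(dates)

    def jitter(scale):
        return 1.0 + (0.15 * rng.standard_normal(n) if noise else 0.0) * scale

    r_red = _R_RED0 * jitter(1.0)
    r_swir = _R_SWIR0 * jitter(1.0)
    baseline = r_red + (r_swir - r_red) * _NIR_BASELINE_SLOPE
    r_nir = baseline + FAI_PER_TROPHIC * lat * jitter(0.3)
    r_green = (_R_GREEN0 + 0.015 * np.tanh(lat)) * jitter(0.5)
    r_blue = (_R_BLUE0 - 0.012 * np.tanh(lat)) * jitter(0.5)

    out = pd.DataFrame(
        {
            "r_blue": np.clip(r_blue, 1e-4, 1.0),
            "r_green": np.clip(r_green, 1e-4, 1.0),
            "r_red": np.clip(r_red, 0.0, 1.0),
            "r_nir": np.clip(r_nir, 0.0, 1.0),
            "r_swir": np.clip(r_swir, 0.0, 1.0),
        },
        index=dates,
    )
    return out


def default_g(trophic, solar, solar_max, c1: float = 0.15, c2: float = 1.0):
    """Bounded supersaturation factor: ``c1 * tanh(c2*trophic) * solar/solar_max``."""
    return c1 * np.tanh(c2 * np.asarray(trophic, dtype=float)) * (
        np.asarray(solar, dtype=float) / solar_max
    )


def make_true_do(
    lake: LakeMeta,
    climate: pd.DataFrame,
    trophic: pd.Series,
    cfg: SyntheticConfig,
    *,
    g=None,
    lake_index: int | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """Ground-truth surface DO: solubility modulated by the trophic factor.

    ``true_do = DOsol(T, P) * (1 + g) + N(0, noise_sd_do)``, floored just
    above zero.  ``g=None`` uses :func:`default_g`; pass ``g=0`` (or any
    array/scalar) to force the pure-saturation limit.
    """
    if not climate.index.equals(trophic.index):
        raise AlignmentError("climate and trophic series must share dates")
    idx = int(lake.lake_id[1:]) if lake_index is None else lake_index
    rng = _rng(cfg, 4, idx)

    t_clip = np.clip(
        climate["air_temperature"].to_numpy(), *SOLUBILITY_T_CLIP
    )
    dosol = oxygen_physics.solubility(t_clip, climate["pressure"].to_numpy())
    if g is None:
        solar = climate["solar"].to_numpy()
        gvals = default_g(
            trophic.to_numpy(), solar, max(solar.max(), 1e-9),
            cfg.supersat_c1, cfg.supersat_c2,
        )
    else:
        gvals = np.broadcast_to(np.asarray(g, dtype=float), (len(climate),))

    true_do = dosol * (1.0 + gvals)
    if noise and cfg.noise_sd_do > 0:
        true_do = true_do + rng.normal(0.0, cfg.noise_sd_do, size=len(true_do))
    return pd.DataFrame(
        {
            "true_do": np.maximum(true_do, 0.05),
            "do_sol": dosol,
            "g": gvals,
            "latent_trophic": trophic.to_numpy(),
            "heatwave_flag": climate["heatwave_flag"].to_numpy(),
        },
        index=climate.index,
    )


def make_observations(
    lake: LakeMeta,
    truth: pd.DataFrame,
    cfg: SyntheticConfig,
    *,
    lake_index: int | None = None,
    noise: bool = True,
    surveys_per_year: float | None = None,
) -> pd.DataFrame:
    """Sparse in situ survey observations of true DO.

    Survey dates are an irregular subsample (``surveys_per_year`` on
    average); observation times sit at local noon +/- 30 min so the 1-h
    climate window is exercised; observed DO carries ``obs_noise_sd``
    Gaussian meter error.  Columns: time, do_obs.
    """
    idx = int(lake.lake_id[1:]) if lake_index is None else lake_index
    rng = _rng(cfg, 5, idx)
    rate = cfg.surveys_per_year if surveys_per_year is None else surveys_per_year
    keep = rng.random(len(truth)) < rate / DAYS_PER_YEAR
    sub = truth.loc[keep]
    n = len(sub)
    minutes = rng.uniform(-30.0, 30.0, size=n)
    times = pd.DatetimeIndex(sub.index) + pd.Timedelta(hours=12) + pd.to_timedelta(
        minutes, unit="m"
    )
    do_obs = sub["true_do"].to_numpy()
    if noise and cfg.obs_noise_sd > 0:
        do_obs = do_obs + rng.normal(0.0, cfg.obs_noise_sd, size=n)
    return pd.DataFrame(
        {"time": times, "do_obs": do_obs, "date": sub.index}
    ).reset_index(drop=True)


def make_path_cohort(
    n_lakes: int,
    *,
    n_years: int = 21,
    start_year: int = 2003,
    b_t: float = -0.85,
    b_wind: float = 0.25,
    b_pressure: float = 0.05,
    b_t_fai: float = 0.3,
    w_sol: float = 0.75,
    w_fai: float = -0.3,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Annual cohorts with known standardized path weights.

    Drivers (t, wind, pressure) are independent standard normals; each
    response is built with exactly unit population variance (residual SD
    chosen to top variance up to 1), so the generating weights ARE the
    population standardized path coefficients::

        dosol = b_t*t + b_wind*wind + b_pressure*pressure + resid
        fai   = b_t_fai*t + resid
        do    = w_sol*dosol + w_fai*fai + resid

    ``noise_scale`` multiplies every residual SD (1 = unit-variance
    construction; 0 = deterministic responses, exact recovery).  Returns
    one (year, do, dosol, fai, t, wind, pressure) frame per lake.
    """
    var_sol = b_t**2 + b_wind**2 + b_pressure**2
    var_fai = b_t_fai**2
    rho = b_t * b_t_fai  # population corr(dosol, fai)
    var_do = w_sol**2 + w_fai**2 + 2.0 * w_sol * w_fai * rho
    if max(var_sol, var_fai, var_do) > 1.0:
        raise ValueError("path weights imply explained variance > 1")
    sd_sol = noise_scale * np.sqrt(1.0 - var_sol)
    sd_fai = noise_scale * np.sqrt(1.0 - var_fai)
    sd_do = noise_scale * np.sqrt(1.0 - var_do)

    years = np.arange(start_year, start_year + n_years)
    out = []
    for i in range(n_lakes):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 901, i])
        t = rng.standard_normal(n_years)
        wind = rng.standard_normal(n_years)
        pressure = rng.standard_normal(n_years)
        dosol = (
            b_t * t + b_wind * wind + b_pressure * pressure
            + sd_sol * rng.standard_normal(n_years)
        )
        fai = b_t_fai * t + sd_fai * rng.standard_normal(n_years)
        do = w_sol * dosol + w_fai * fai + sd_do * rng.standard_normal(n_years)
        out.append(
            pd.DataFrame(
                {
                    "year": years,
                    "do": do,
                    "dosol": dosol,
                    "fai": fai,
                    "t": t,
                    "wind": wind,
                    "pressure": pressure,
                }
            )
        )
    return out


def make_trend_series(
    n_lakes: int,
    trend_per_decade: float,
    *,
    years: int = 21,
    start_year: int = 2003,
    base_do: float = 9.5,
    seasonal_amp: float = 1.5,
    noise_sd: float = 0.5,
    ar_coef: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily DO cohort with a known imposed trend, for trend-recovery runs.

    Each lake gets ``base_do + trend*decades + seasonal cycle + AR(1)
    noise``; hemisphere alternates so both summer windows are exercised.
    Returns a tidy frame (lake_id, date, do, hemisphere).
    """
    dates = pd.date_range(f"{start_year}-01-01", periods=round(years * 365.25), freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    decades = (dates - dates[0]).days.to_numpy() / DAYS_PER_YEAR / 10.0
    frames = []
    for i in range(n_lakes):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 900, i])
        hemi = "N" if i % 2 == 0 else "S"
        peak = 20.0 if hemi == "N" else 200.0  # DO peaks in local winter
        seas = seasonal_amp * np.cos(2.0 * np.pi * (doy - peak) / DAYS_PER_YEAR)
        noise = _ar1(rng, len(dates), noise_sd, ar_coef)
        do = base_do + trend_per_decade * decades + seas + noise
        frames.append(
            pd.DataFrame(
                {"lake_id": f"T{i:04d}", "date": dates, "do": do, "hemisphere": hemi}
            )
        )
    return pd.concat(frames, ignore_index=True)
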