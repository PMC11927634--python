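"""Oxygen solubility and saturation-departure physics.

Surface dissolved oxygen (DO) in a lake can be decomposed into the
equilibrium (solubility) component set by air temperature and pressure,
and the biological/biogeochemical departure from 100% saturation driven
by photosynthesis, respiration and gas exchange.  This module provides:

* ``solubility`` — equilibrium freshwater DO concentration (mg/L) from the
  Benson–Krause formulation with the standard barometric pressure
  correction (the USGS convention for zero-salinity water);
* ``do_sp`` — signed percent departure of a DO concentration from 100%
  saturation (positive = supersaturation);
* ``seasonal_amplitude`` — max-minus-min of monthly mean DO;
* ``pressure_from_elevation`` — barometric proxy for surface pressure when
  no reanalysis pressure field is available.

All functions are vectorised over numpy arrays / pandas Series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "solubility",
    "do_sp",
    "percent_of_saturation",
    "seasonal_amplitude",
    "pressure_from_elevation",
    "OxygenState",
    "SeasonalProfile",
]

# Valid temperature range for the solubility fit (deg C).
T_MIN_C = -2.0
T_MAX_C = 45.0


@dataclass(frozen=True)
class OxygenState:
    """DO concentration with its companion solubility and departure."""

    do_conc: float  # mg/L
    do_sol: float   # mg/L
    do_sp: float    # percent departure from saturation


@dataclass
class SeasonalProfile:
    """Twelve monthly mean DO values and their seasonal amplitude."""

    monthly_means: np.ndarray     # length 12, NaN for missing months
    delta_do: float               # max - min over valid months (mg/L)
    n_valid: int
    defined: bool                 # False when < 2 valid months


def _vapour_pressure_atm(temp_k: np.ndarray) -> np.ndarray:
    # Saturated water-vapour pressure (atm) used in the pressure correction.
    return np.exp(11.8571 - 3840.70 / temp_k - 216961.0 / temp_k**2)


def solubility(temperature_c, pressure_atm=1.0):
    """Equilibrium DO concentration of freshwater (mg/L).

    Benson–Krause fit at 1 atm total pressure (water-vapour saturated air,
    zero salinity), scaled by the standard pressure-correction factor

    ``F = P * (1 - u/P) * (1 - theta*P) / ((1 - u) * (1 - theta))``

    with ``u`` the vapour pressure (atm) and ``theta`` a weak quadratic in
    temperature.  Strictly decreasing in temperature on [0, 45] degC and
    increasing in pressure.

    Parameters
    ----------
    temperature_c : array_like
        Air/surface temperature in degrees Celsius, within [-2, 45].
    pressure_atm : array_like, optional
        Total atmospheric pressure in standard atmospheres (default 1).

    Raises
    ------
    ValueError
        If any temperature is outside [-2, 45] degC or pressure <= 0.
    """
    t = np.asarray(temperature_c, dtype=float)
    p = np.asarray(pressure_atm, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < T_MIN_C) or np.any(t > T_MAX_C):
        raise ValueError(
            f"temperature must be finite and within [{T_MIN_C}, {T_MAX_C}] degC"
        )
    if np.any(~np.isfinite(p)) or np.any(p <= 0):
        raise ValueError("pressure must be finite and > 0 atm")

    tk = t + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / tk
        - 6.642308e7 / tk**2
        + 1.243800e10 / tk**3
        - 8.621949e11 / tk**4
    )
    c_star = np.exp(ln_c)  # mg/L at 1 atm

    u = _vapour_pressure_atm(tk)
    theta = 0.000975 - 1.426e-5 * t + 6.436e-8 * t**2
    factor = p * (1.0 - u / p) * (1.0 - theta * p) / ((1.0 - u) * (1.0 - theta))
    out = c_star * factor
    if out.ndim == 0:
        return float(out)
    return out


def do_sp(do_conc, do_sol):
    """Signed percent departure of DO from 100% saturation.

    ``100 * (do_conc - do_sol) / do_sol``; positive values indicate
    supersaturation (net oxygen production), negative values net
    consumption.
    """
    conc = np.asarray(do_conc, dtype=float)
    sol = np.asarray(do_sol, dtype=float)
    if np.any(sol <= 0):
        raise ValueError("do_sol must be > 0")
    out = 100.0 * (conc - sol) / sol
    if out.ndim == 0:
        return float(out)
    return out


def percent_of_saturation(do_conc, do_sol):
    """Alternative convention: DO as a percentage of saturation (100 = saturated)."""
    conc = np.asarray(do_conc, dtype=float)
    sol = np.asarray(do_sol, dtype=float)
    if np.any(sol <= 0):
        raise ValueError("do_sol must be > 0")
    out = 100.0 * conc / sol
    if out.ndim == 0:
        return float(out)
    return out


def seasonal_amplitude(monthly_means) -> SeasonalProfile:
    """Seasonal DO fluctuation: max minus min of the 12 monthly means.

    Missing (sub-zero-masked) months are passed as NaN.  With fewer than
    two valid months the amplitude is undefined and flagged.
    """
    m = np.asarray(monthly_means, dtype=float)
    if m.shape != (12,):
        raise ValueError("expected exactly 12 monthly values (NaN for missing)")
    valid = np.isfinite(m)
    n_valid = int(valid.sum())
    if n_valid < 2:
        return SeasonalProfile(m, float("nan"), n_valid, defined=False)
    delta = float(np.nanmax(m) - np.nanmin(m))
    return SeasonalProfile(m, delta, n_valid, defined=True)


def pressure_from_elevation(elevation_m):
    """Surface pressure (atm) from elevation via the barometric formula.

    International standard atmosphere: ``(1 - 2.25577e-5 h)**5.25588``.
    """
    h = np.asarray(elevation_m, dtype=float)
    out = (1.0 - 2.25577e-5 * h) ** 5.25588
    if out.ndim == 0:
        return float(out)
    return out
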