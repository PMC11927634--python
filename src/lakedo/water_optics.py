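"""Water-colour indices and water-identification filters.

Two multispectral indices proxy lake trophic state:

* **FAI** (floating algae index): NIR reflectance minus the linear
  red–SWIR baseline interpolated to the NIR band centre,
  ``FAI = R(NIR) - R(red) - (R(SWIR) - R(red)) * (859-645)/(1240-645)``,
  with band centres fixed at 645 nm (red), 859 nm (NIR), 1240 nm (SWIR).
  High FAI flags dense surface phytoplankton.
* **Hue angle** ``a'``: the angle of the water's CIE chromaticity
  coordinates (x, y) around the white point, computed from the
  red/green/blue tristimulus transform, with a degree-5 polynomial
  correction ``delta_a`` applied to the raw angle.

Also implemented are the mask-building filters used before index
extraction: NDWI with Otsu histogram-splitting, an optical-depth (OD)
mask, occurrence-frequency screening, one-pixel inward erosion and a
minimum connected-component size, plus the 3x3-window coefficient-of-
variation gate used when matching satellite samples to field samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "fai",
    "hue_angle",
    "ndwi",
    "ndwi_mask",
    "apply_filters",
    "window_cv",
    "ChromaticityState",
    "WindowStats",
    "WAVELENGTH_RED_NM",
    "WAVELENGTH_NIR_NM",
    "WAVELENGTH_SWIR_NM",
]

WAVELENGTH_RED_NM = 645.0
WAVELENGTH_NIR_NM = 859.0
WAVELENGTH_SWIR_NM = 1240.0

# White point of the chromaticity plane; the hue angle is measured around
# this point. 0.33 as printed in the source transform (not 1/3 exactly).
WHITE_POINT = 0.33

# Coefficients of the hue-correction polynomial in s = a/100, degree 5 -> 0.
_DELTA_A_COEFFS = (-1.8185, -62.461, 320.49, -510.97, 306.32, -50.343)

# 4-connected structuring element, used for both erosion and labelling.
_CROSS = ndimage.generate_binary_structure(2, 1)


def fai(r_nir, r_red, r_swir):
    """Floating algae index from NIR, red and SWIR reflectance.

    Linear and homogeneous in the bands; zero for a flat spectrum.
    Raises ``ValueError`` on negative or non-finite reflectance.
    """
    nir = np.asarray(r_nir, dtype=float)
    red = np.asarray(r_red, dtype=float)
    swir = np.asarray(r_swir, dtype=float)
    for name, band in (("r_nir", nir), ("r_red", red), ("r_swir", swir)):
        if np.any(~np.isfinite(band)) or np.any(band < 0):
            raise ValueError(f"{name} must be finite and >= 0")
    slope = (WAVELENGTH_NIR_NM - WAVELENGTH_RED_NM) / (
        WAVELENGTH_SWIR_NM - WAVELENGTH_RED_NM
    )
    out = nir - red - (swir - red) * slope
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ChromaticityState:
    """Tristimulus values, chromaticity coordinates and hue angles."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    x: np.ndarray
    y: np.ndarray
    a: np.ndarray          # uncorrected hue angle, degrees
    delta_a: np.ndarray    # polynomial correction, degrees
    a_prime: np.ndarray    # corrected hue angle = a - delta_a
    undefined: np.ndarray  # True where (x, y) sits on the white point


def _delta_a(a_deg: np.ndarray) -> np.ndarray:
    s = a_deg / 100.0
    c5, c4, c3, c2, c1, c0 = _DELTA_A_COEFFS
    return c5 * s**5 + c4 * s**4 + c3 * s**3 + c2 * s**2 + c1 * s + c0


def hue_angle(r_red, r_green, r_blue) -> ChromaticityState:
    """Chromaticity hue angle from red/green/blue water-leaving reflectance.

    Tristimulus values::

        X = 2.7689 R(red) + 1.7517 R(green) + 1.1302 R(blue)
        Y = 1.0000 R(red) + 4.5906 R(green) + 0.0601 R(blue)
        Z =                 0.0565 R(green) + 5.5943 R(blue)

    then ``x = X/(X+Y+Z)``, ``y = Y/(X+Y+Z)`` and the hue angle

        ``a = atan2(x - 0.33, y - 0.33) * 180/pi + 180``

    (arguments stacked numerator-over-denominator, yielding a in (0, 360]),
    followed by the polynomial correction ``a' = a - delta_a(a/100)``.

    Scale-invariant: multiplying all bands by k > 0 leaves x, y, a, a'
    unchanged.  Samples whose chromaticity falls exactly on the white
    point have an undefined hue and are flagged (NaN angles).  All-zero
    band triples raise ``ValueError``.
    """
    red = np.atleast_1d(np.asarray(r_red, dtype=float))
    green = np.atleast_1d(np.asarray(r_green, dtype=float))
    blue = np.atleast_1d(np.asarray(r_blue, dtype=float))
    scalar = np.asarray(r_red).ndim == 0
    for name, band in (("r_red", red), ("r_green", green), ("r_blue", blue)):
        if np.any(~np.isfinite(band)) or np.any(band < 0):
            raise ValueError(f"{name} must be finite and >= 0")

    X = 2.7689 * red + 1.7517 * green + 1.1302 * blue
    Y = 1.0000 * red + 4.5906 * green + 0.0601 * blue
    Z = 0.0565 * green + 5.5943 * blue
    total = X + Y + Z
    if np.any(total == 0):
        raise ValueError("all-zero band triple: tristimulus sum is zero")

    x = X / total
    y = Y / total
    undefined = (x == WHITE_POINT) & (y == WHITE_POINT)

    a = np.degrees(np.arctan2(x - WHITE_POINT, y - WHITE_POINT)) + 180.0
    a = np.where(undefined, np.nan, a)
    da = _delta_a(a)
    a_prime = a - da

    if scalar:
        def _s(v):
            return v.reshape(())[()]
        return ChromaticityState(
            _s(X), _s(Y), _s(Z), _s(x), _s(y), _s(a), _s(da), _s(a_prime),
            bool(undefined[0]),
        )
    return ChromaticityState(X, Y, Z, x, y, a, da, a_prime, undefined)


def ndwi(green, nir):
    """Normalized difference water index ``(green - NIR)/(green + NIR)``.

    Pixels where both bands are zero are returned as NaN (invalid).
    """
    g = np.asarray(green, dtype=float)
    n = np.asarray(nir, dtype=float)
    denom = g + n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (g - n) / denom, np.nan)
    return out


def ndwi_mask(green, nir):
    """Water mask by Otsu histogram-splitting of the NDWI field.

    Returns ``(mask, threshold)``; the mask is True where
    ``NDWI >= threshold``.  A degenerate (constant) NDWI histogram has no
    split: the threshold is NaN and the mask is all-True with a warning.
    Invalid pixels (zero-sum bands) are False in the mask.
    """
    from skimage.filters import threshold_otsu

    index = ndwi(green, nir)
    valid = np.isfinite(index)
    vals = index[valid]
    if vals.size == 0:
        warnings.warn("no valid NDWI pixels; empty mask")
        return np.zeros_like(index, dtype=bool), float("nan")
    if np.all(vals == vals.flat[0]):
        warnings.warn("degenerate NDWI histogram (constant); mask set all-true")
        mask = np.ones_like(index, dtype=bool)
        mask[~valid] = False
        return mask, float("nan")
    thresh = float(threshold_otsu(vals))
    mask = np.zeros_like(index, dtype=bool)
    mask[valid] = index[valid] >= thresh
    return mask, thresh


def apply_filters(
    mask,
    od_field=None,
    occurrence_field=None,
    *,
    min_od: float = 20.0,
    min_occurrence: float = 0.70,
    min_component_px: int = 4,
    erode: bool = True,
):
    """Refine a water mask with the OD / occurrence / erosion / size rules.

    Steps, in order: drop optically shallow pixels (OD < ``min_od``);
    keep permanent water (occurrence > ``min_occurrence``); erode the mask
    inward by one pixel (4-connectivity) against land-adjacency effects;
    drop 4-connected components smaller than ``min_component_px`` pixels.
    """
    m = np.asarray(mask, dtype=bool)
    if od_field is not None:
        od = np.asarray(od_field, dtype=float)
        if od.shape != m.shape:
            raise ValueError("od_field shape mismatch")
        m = m & (od >= min_od)
    if occurrence_field is not None:
        occ = np.asarray(occurrence_field, dtype=float)
        if occ.shape != m.shape:
            raise ValueError("occurrence_field shape mismatch")
        m = m & (occ > min_occurrence)
    if erode:
        m = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    labels, n_comp = ndimage.label(m, structure=_CROSS)
    if n_comp:
        sizes = np.bincount(labels.ravel())
        small = sizes < min_component_px
        small[0] = False
        m = m & ~small[labels]
    return m


@dataclass
class WindowStats:
    """3x3-window aggregation with its homogeneity verdict."""

    mean: float
    cv: float
    passed: bool
    degenerate: bool


def window_cv(values, *, max_cv: float = 0.10, ddof: int = 0) -> WindowStats:
    """Homogeneity gate for a 3x3 pixel window.

    The window passes iff the coefficient of variation SD/mean is
    strictly below ``max_cv`` (default 10%); the reported value is the
    window mean.  Population SD (ddof=0) by default: the nine pixels are
    the whole neighbourhood, not a sample.  A zero-mean window is
    degenerate and fails.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size != 9 or np.any(~np.isfinite(v)):
        raise ValueError("expected nine finite values")
    mean = float(v.mean())
    if mean == 0:
        return WindowStats(mean=0.0, cv=float("nan"), passed=False, degenerate=True)
    cv = float(v.std(ddof=ddof) / abs(mean))
    return WindowStats(mean=mean, cv=cv, passed=cv < max_cv, degenerate=False)
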