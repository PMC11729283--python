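"""DRS calibration, oxygenation ratiometry and CIE 1931 pseudo-colour.

A diffuse-reflectance spectrum of perfused tissue carries the hemoglobin
absorption bands: oxyhemoglobin dips at 540 and 575 nm, deoxyhemoglobin a
single dip near 555 nm.  Two summaries are computed here:

* the reflectance ratio R(555) / (R(540) + R(575)), each R being the mean
  reflectance in a 5 nm band, which rises with oxygen saturation, and
* a single pseudo-colour per spectrum, by integrating the reflectance
  against the CIE 1931 2-degree colour-matching functions under D65
  illumination and converting the tristimulus values to sRGB.

The colour-matching functions are an analytic multi-lobe Gaussian
approximation of the standard observer; D65 is embedded as a 10 nm
tabulation and interpolated.  The XYZ -> RGB step is white-balanced to the
embedded illuminant so a perfect reflector maps exactly to RGB (1, 1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io_core import AnalysisError, CalibrationError, SpectrumRecord

# Relative spectral power of the D65 daylight illuminant, 380-780 nm at
# 10 nm steps, normalised to 100 at 560 nm.
_D65_10NM = np.array([
    49.98, 54.65, 82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81,
    114.86, 115.92, 108.81, 109.35, 107.80, 104.79, 107.69, 104.41,
    104.05, 100.00, 96.33, 95.79, 88.69, 90.01, 89.60, 87.70, 83.29,
    83.70, 80.03, 80.21, 82.28, 78.28, 69.72, 71.61, 74.35, 61.60,
    69.89, 75.09, 63.59, 46.42, 66.81, 63.38,
])
_D65_GRID = np.arange(380.0, 781.0, 10.0)

# Linear sRGB primaries (D65 white), IEC 61966-2-1.
_XYZ_TO_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


@dataclass
class CMFTable:
    """CIE 1931 2-degree observer curves and D65 power on a shared grid."""

    wavelength_nm: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    d65: np.ndarray


@dataclass
class RatioSeries:
    """Reflectance-ratio time series with smoothed values and pseudo-colours."""

    time_s: np.ndarray
    ratio: np.ndarray
    smoothed: np.ndarray
    rgb: np.ndarray  # (N, 3) in [0, 1]


def _lobe(wl: np.ndarray, centre: float, sig_lo: float, sig_hi: float) -> np.ndarray:
    sig = np.where(wl < centre, sig_lo, sig_hi)
    return np.exp(-0.5 * ((wl - centre) / sig) ** 2)


@lru_cache(maxsize=4)
def cie_1931_table(step_nm: float = 5.0) -> CMFTable:
    """Build the colour-matching / illuminant table on a 380-780 nm grid.

    Uses the piecewise-Gaussian analytic fit of the 1931 observer (three
    lobes for xbar, two each for ybar and zbar), accurate to about 1% of
    peak, with ybar peaking near 555 nm.
    """
    wl = np.arange(380.0, 780.0 + 0.5 * step_nm, step_nm)
    xbar = (1.056 * _lobe(wl, 599.8, 37.9, 31.0)
            + 0.362 * _lobe(wl, 442.0, 16.0, 26.7)
            - 0.065 * _lobe(wl, 501.1, 20.4, 26.2))
    ybar = (0.821 * _lobe(wl, 568.8, 46.9, 40.5)
            + 0.286 * _lobe(wl, 530.9, 16.3, 31.1))
    zbar = (1.217 * _lobe(wl, 437.0, 11.8, 36.0)
            + 0.681 * _lobe(wl, 459.0, 26.0, 13.8))
    xbar = np.clip(xbar, 0.0, None)
    d65 = np.interp(wl, _D65_GRID, _D65_10NM)
    return CMFTable(wl, xbar, ybar, zbar, d65)


def calibrate(raw: SpectrumRecord, dark: SpectrumRecord,
              reference: SpectrumRecord,
              analysis_range: tuple[float, float] = (450.0, 800.0),
              ) -> SpectrumRecord:
    """Reflectance calibration R = (S - D) / (Ref - D) against a white target.

    Raises :class:`CalibrationError` when the reference does not exceed the
    dark anywhere on the analysis range; the result is clipped below at 0.
    """
    wl = raw.wavelength_nm
    for other in (dark, reference):
        if not np.allclose(other.wavelength_nm, wl):
            raise CalibrationError("raw/dark/reference grids differ")
    denom = reference.values - dark.values
    in_range = (wl >= analysis_range[0]) & (wl <= analysis_range[1])
    bad = in_range & (denom <= 0)
    if np.any(bad):
        offending = wl[bad]
        raise CalibrationError(
            "reference <= dark at "
            f"{offending.size} wavelengths (first few: {offending[:5].tolist()})")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, (raw.values - dark.values) / denom, 0.0)
    return SpectrumRecord(wl, np.clip(values, 0.0, None),
                          time_s=raw.time_s, kind="calibrated")


def band_mean(spectrum: SpectrumRecord, centre_nm: float,
              width_nm: float = 5.0) -> float:
    """Mean of the samples within centre +- width/2 nm, inclusive."""
    wl = spectrum.wavelength_nm
    mask = (wl >= centre_nm - width_nm / 2) & (wl <= centre_nm + width_nm / 2)
    if not np.any(mask):
        raise AnalysisError(
            f"no samples in the {centre_nm} +- {width_nm / 2} nm band")
    return float(spectrum.values[mask].mean())


def reflectance_ratio(spectrum: SpectrumRecord, width_nm: float = 5.0) -> float:
    """Oxygenation ratio R(555) / (R(540) + R(575)) over 5 nm bands."""
    num = band_mean(spectrum, 555.0, width_nm)
    den = band_mean(spectrum, 540.0, width_nm) + band_mean(spectrum, 575.0, width_nm)
    if den == 0:
        raise AnalysisError("zero denominator in reflectance ratio")
    return num / den


def average_spectra(records: list[SpectrumRecord],
                    window_s: float) -> list[SpectrumRecord]:
    """Pointwise means over non-overlapping time windows of width window_s.

    Windows are anchored at the first record's timestamp; each output record
    is stamped with the mean time of its members (the window centre for a
    uniformly filled window).
    """
    if not records:
        return []
    wl = records[0].wavelength_nm
    t0 = records[0].time_s
    bins: dict[int, list[SpectrumRecord]] = {}
    for rec in records:
        bins.setdefault(int((rec.time_s - t0) // window_s), []).append(rec)
    out = []
    for key in sorted(bins):
        members = bins[key]
        values = np.mean([m.values for m in members], axis=0)
        t = float(np.mean([m.time_s for m in members]))
        out.append(SpectrumRecord(wl, values, time_s=t, kind=members[0].kind))
    return out


def smooth_series(values: np.ndarray, window_n: int) -> np.ndarray:
    """Centred moving average with the window shrinking at the edges."""
    if window_n < 1 or window_n % 2 == 0:
        raise ValueError("window_n must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    half = window_n // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = values.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def spectrum_to_xyz(spectrum: SpectrumRecord,
                    cmf: CMFTable | None = None) -> tuple[float, float, float]:
    """Integrate reflectance against D65-weighted matching functions.

    Normalised so that a perfect reflector (R = 1 everywhere) has Y = 1
    exactly; linear in the reflectance.
    """
    cmf = cmf or cie_1931_table()
    wl = spectrum.wavelength_nm
    lo = max(wl[0], cmf.wavelength_nm[0])
    hi = min(wl[-1], cmf.wavelength_nm[-1])
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 2:
        raise AnalysisError("spectrum does not overlap the 380-780 nm CMF grid")
    grid = wl[mask]
    refl = spectrum.values[mask]
    xb = np.interp(grid, cmf.wavelength_nm, cmf.xbar)
    yb = np.interp(grid, cmf.wavelength_nm, cmf.ybar)
    zb = np.interp(grid, cmf.wavelength_nm, cmf.zbar)
    d65 = np.interp(grid, cmf.wavelength_nm, cmf.d65)
    norm = np.trapezoid(d65 * yb, grid)
    x = np.trapezoid(refl * d65 * xb, grid) / norm
    y = np.trapezoid(refl * d65 * yb, grid) / norm
    z = np.trapezoid(refl * d65 * zb, grid) / norm
    return float(x), float(y), float(z)


def white_point(cmf: CMFTable | None = None) -> np.ndarray:
    """Tristimulus values of a perfect reflector under the embedded D65."""
    cmf = cmf or cie_1931_table()
    flat = SpectrumRecord(cmf.wavelength_nm, np.ones_like(cmf.wavelength_nm),
                          time_s=0.0, kind="calibrated")
    return np.array(spectrum_to_xyz(flat, cmf))


def _srgb_gamma(linear: np.ndarray) -> np.ndarray:
    linear = np.clip(linear, 0.0, None)
    return np.where(linear <= 0.0031308,
                    12.92 * linear,
                    1.055 * np.power(linear, 1 / 2.4) - 0.055)


def xyz_to_rgb(xyz, cmf: CMFTable | None = None) -> np.ndarray:
    """XYZ -> sRGB (linear matrix, white-balanced to D65, gamma, clip).

    The linear channels are divided by the channels of the embedded-D65
    white point so the white point maps exactly to (1, 1, 1); out-of-gamut
    values are clipped after gamma encoding.
    """
    xyz = np.asarray(xyz, dtype=float)
    white = _XYZ_TO_SRGB @ white_point(cmf)
    linear = (_XYZ_TO_SRGB @ xyz) / white
    return np.clip(_srgb_gamma(linear), 0.0, 1.0)


def spectrum_to_rgb(spectrum: SpectrumRecord,
                    cmf: CMFTable | None = None) -> np.ndarray:
    """Convenience composition of spectrum_to_xyz and xyz_to_rgb."""
    return xyz_to_rgb(spectrum_to_xyz(spectrum, cmf), cmf)


def ratio_timeseries(records: list[SpectrumRecord],
                     smooth_window: int = 31,
                     colour_window_s: float = 1.0,
                     width_nm: float = 5.0,
                     cmf: CMFTable | None = None) -> RatioSeries:
    """Per-record oxygenation ratio, its moving average, and pseudo-colours.

    Colours are computed from spectra averaged over ``colour_window_s``
    (1 s by default, which removes the heartbeat ripple) and each record is
    assigned the colour of the window it falls in.
    """
    if not records:
        raise AnalysisError("no spectra given")
    times = np.array([r.time_s for r in records])
    ratios = np.array([reflectance_ratio(r, width_nm) for r in records])
    smoothed = smooth_series(ratios, smooth_window)
    averaged = average_spectra(records, colour_window_s)
    colours = np.array([spectrum_to_rgb(a, cmf) for a in averaged])
    keys = sorted({int((r.time_s - times[0]) // colour_window_s) for r in records})
    remap = {k: i for i, k in enumerate(keys)}
    rgb = colours[[remap[int((t - times[0]) // colour_window_s)] for t in times]]
    return RatioSeries(time_s=times, ratio=ratios, smoothed=smoothed, rgb=rgb)


_RED = np.array([1.0, 0.0, 0.0])
_AMBER = np.array([1.0, 0.75, 0.0])
_GREEN = np.array([0.0, 1.0, 0.0])


def traffic_light(ratio: float, t_low: float, t_high: float) -> np.ndarray:
    """Map a ratio to a red / amber / green indicator colour.

    At or below ``t_low`` the colour is red, at or above ``t_high`` green,
    and in between the colour interpolates linearly through amber at the
    midpoint.
    """
    if not t_low < t_high:
        raise ValueError("need t_low < t_high")
    if ratio <= t_low:
        return _RED.copy()
    if ratio >= t_high:
        return _GREEN.copy()
    mid = 0.5 * (t_low + t_high)
    if ratio <= mid:
        f = (ratio - t_low) / (mid - t_low)
        return (1 - f) * _RED + f * _AMBER
    f = (ratio - mid) / (t_high - mid)
    return (1 - f) * _AMBER + f * _GREEN
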