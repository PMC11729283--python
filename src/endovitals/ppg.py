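"""ROI-mean HSV time series and Fourier vital-sign estimation.

The back-scattered intensity inside the catheter lumen pulses with blood
volume, so the ROI-mean value (V) channel of a stabilised endoscope video
is a photoplethysmogram: its amplitude spectrum shows one peak at the
heart rate and one at the respiration rate.  Frames without a valid
circle fit (blood incursion) are flagged and linearly interpolated before
the FFT; the series is detrended with a moving average, Hann-windowed,
and the band peaks are located with parabolic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from skimage.color import rgb2hsv

from .io_core import AnalysisError, Frame, VideoSequence
from .roi import CircleROI, RoiParams, roi_mask


@dataclass
class PPGSeries:
    """Per-frame ROI-mean H, S, V with a validity mask."""

    time_s: np.ndarray
    h: np.ndarray
    s: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    fps: float

    def channel(self, name: str) -> np.ndarray:
        if name not in ("h", "s", "v"):
            raise ValueError("channel must be one of 'h', 's', 'v'")
        return getattr(self, name)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.time_s.size else 0.0


@dataclass
class VitalSigns:
    """Estimated heart and respiration rates (None when no peak stands out)."""

    hr_bpm: float | None
    rr_bpm: float | None
    hr_peak_height: float | None
    rr_peak_height: float | None
    channel: str


@dataclass
class PpgParams:
    """Vital-sign estimation tunables.

    The headline channel is V; the cardiac and respiratory search bands
    default to 40-200 and 5-30 beats/min; a band peak counts only if it
    exceeds ``noise_floor`` times the median spectral magnitude in its
    band.
    """

    channel: str = "v"
    detrend_window_s: float = 10.0
    cardiac_band_bpm: tuple[float, float] = (40.0, 200.0)
    resp_band_bpm: tuple[float, float] = (5.0, 30.0)
    noise_floor: float = 4.0


def rgb_to_hsv(frame: Frame | np.ndarray) -> np.ndarray:
    """Standard hexcone RGB -> HSV; H in [0, 1) and 0 for achromatic pixels."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    return rgb2hsv(pixels)


def extract_ppg(video: VideoSequence, circles: list[CircleROI],
                params: RoiParams | None = None) -> PPGSeries:
    """ROI-mean H, S, V per frame; invalid frames flagged with NaN values."""
    params = params or RoiParams()
    if len(circles) != len(video):
        raise AnalysisError("need exactly one circle per frame")
    n = len(video)
    h = np.full(n, np.nan)
    s = np.full(n, np.nan)
    v = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    height, width = video.shape
    for i, (frame, circle) in enumerate(zip(video.frames, circles)):
        if not circle.valid:
            continue
        mask = roi_mask(circle, params.shrink, height, width)
        if not mask.any():
            continue
        hsv = rgb_to_hsv(frame)[mask]
        h[i], s[i], v[i] = hsv.mean(axis=0)
        valid[i] = True
    if not valid.any():
        raise AnalysisError("no valid frames in the sequence")
    return PPGSeries(time_s=video.times, h=h, s=s, v=v, valid=valid,
                     fps=video.fps)


def _fill_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    good = np.flatnonzero(valid)
    if good.size < 2:
        raise AnalysisError("need at least 2 valid samples")
    idx = np.arange(values.size)
    return np.interp(idx, good, values[good])  # edges held at nearest valid


def _moving_average(values: np.ndarray, window_n: int) -> np.ndarray:
    half = window_n // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = values.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def detrend(values: np.ndarray, valid: np.ndarray, window_s: float,
            fps: float) -> np.ndarray:
    """Gap-fill, subtract a centred moving average, and remove the mean."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    filled = _fill_invalid(np.asarray(values, dtype=float),
                           np.asarray(valid, dtype=bool))
    window_n = max(1, int(round(window_s * fps)) | 1)  # force odd
    out = filled - _moving_average(filled, window_n)
    return out - out.mean()


def amplitude_spectrum(values: np.ndarray, fps: float,
                       normalise: bool = True
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude of the Hann-windowed DFT, frequencies in beats per minute.

    Normalised to a maximum of 1 unless the series is identically zero (or
    ``normalise=False``, which exposes the raw magnitudes, e.g. for energy
    checks).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 64:
        raise AnalysisError("need at least 64 uniformly sampled values")
    windowed = values * np.hanning(values.size)
    mags = np.abs(np.fft.rfft(windowed))
    freq_bpm = np.fft.rfftfreq(values.size, d=1.0 / fps) * 60.0
    if normalise:
        peak = mags.max()
        if peak > 0:
            mags = mags / peak
    return freq_bpm, mags


def _band_peak(freq_bpm: np.ndarray, mags: np.ndarray,
               band: tuple[float, float],
               noise_floor: float) -> tuple[float, float] | None:
    """Parabolic-interpolated argmax inside a band, or None if no real peak."""
    in_band = np.flatnonzero((freq_bpm >= band[0]) & (freq_bpm <= band[1]))
    if in_band.size == 0:
        return None
    band_mags = mags[in_band]
    k = in_band[int(np.argmax(band_mags))]
    if k == 0 or k == mags.size - 1:
        return None
    if mags[k] < mags[k - 1] or mags[k] < mags[k + 1]:
        return None  # band maximum is not a local maximum
    floor = float(np.median(band_mags))
    if not mags[k] > noise_floor * floor:
        return None
    denom = mags[k - 1] - 2.0 * mags[k] + mags[k + 1]
    delta = 0.0 if denom == 0 else 0.5 * (mags[k - 1] - mags[k + 1]) / denom
    df = freq_bpm[1] - freq_bpm[0]
    return float(freq_bpm[k] + delta * df), float(mags[k])


def estimate_vitals(ppg: PPGSeries, params: PpgParams | None = None
                    ) -> VitalSigns:
    """Heart and respiration rates from the configured channel's spectrum."""
    params = params or PpgParams()
    if ppg.duration_s < 30.0:
        raise AnalysisError("need at least 30 s of video for vital signs")
    series = detrend(ppg.channel(params.channel), ppg.valid,
                     params.detrend_window_s, ppg.fps)
    freq_bpm, mags = amplitude_spectrum(series, ppg.fps)
    hr = _band_peak(freq_bpm, mags, params.cardiac_band_bpm, params.noise_floor)
    rr = _band_peak(freq_bpm, mags, params.resp_band_bpm, params.noise_floor)
    return VitalSigns(hr_bpm=None if hr is None else hr[0],
                      rr_bpm=None if rr is None else rr[0],
                      hr_peak_height=None if hr is None else hr[1],
                      rr_peak_height=None if rr is None else rr[1],
                      channel=params.channel)


def envelope(values: np.ndarray, fps: float,
             smooth_s: float = 0.6) -> np.ndarray:
    """Analytic-signal magnitude smoothed over about one cardiac period."""
    values = np.asarray(values, dtype=float)
    env = np.abs(hilbert(values))
    window_n = max(1, int(round(smooth_s * fps)) | 1)
    return _moving_average(env, window_n)
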