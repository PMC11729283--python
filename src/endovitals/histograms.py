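"""HSV-histogram time series over the ROI and an ischemia shift metric.

Arterial occlusion shifts the distribution of tissue pixel colours - most
visibly in the saturation channel - well before the change is obvious in
the images themselves.  Frames are grouped into consecutive windows of
valid frames (invalid, blood-incursion frames are skipped and not
counted), all ROI pixels of a window are pooled into one normalised
histogram per HSV channel, and a baseline/test comparison summarises the
shift per channel as a mean difference, a standardised effect size and a
total-variation distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import AnalysisError, VideoSequence
from .ppg import rgb_to_hsv
from .roi import CircleROI, RoiParams, roi_mask

_CHANNELS = ("h", "s", "v")


@dataclass
class HSVHistogramSeries:
    """Windowed, normalised HSV histograms with per-window channel means."""

    time_s: np.ndarray            # window centre times
    hist: dict[str, np.ndarray]   # channel -> (n_windows, bins), each row sums to 1
    means: dict[str, np.ndarray]  # channel -> (n_windows,)
    frames_per_window: np.ndarray
    bin_edges: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.time_s.size


@dataclass
class ChannelShift:
    """Baseline-vs-test summary for one HSV channel."""

    mean_diff: float
    pooled_sd: float
    effect: float
    tv_distance: float


def hsv_histogram_series(video: VideoSequence, circles: list[CircleROI],
                         window_frames: int = 20, bins: int = 64,
                         params: RoiParams | None = None,
                         window_seconds: float | None = None,
                         ) -> HSVHistogramSeries:
    """Pool ROI pixels of consecutive valid frames into per-window histograms.

    Windows hold ``window_frames`` valid frames each (a shorter trailing
    window is kept); pass ``window_seconds`` to group by elapsed time
    instead.  Raises when the sequence has no valid frame at all.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    params = params or RoiParams()
    height, width = video.shape
    valid_items = [(f, c) for f, c in zip(video.frames, circles) if c.valid]
    if not valid_items:
        raise AnalysisError("no valid frames in the sequence")
    groups: list[list] = []
    if window_seconds is not None:
        t0 = valid_items[0][0].time_s
        bucket: dict[int, list] = {}
        for item in valid_items:
            bucket.setdefault(int((item[0].time_s - t0) // window_seconds),
                              []).append(item)
        groups = [bucket[k] for k in sorted(bucket)]
    else:
        groups = [valid_items[i:i + window_frames]
                  for i in range(0, len(valid_items), window_frames)]
    edges = np.linspace(0.0, 1.0, bins + 1)
    hists = {ch: np.empty((len(groups), bins)) for ch in _CHANNELS}
    means = {ch: np.empty(len(groups)) for ch in _CHANNELS}
    times = np.empty(len(groups))
    counts = np.empty(len(groups), dtype=int)
    for g, group in enumerate(groups):
        pixels = []
        for frame, circle in group:
            mask = roi_mask(circle, params.shrink, height, width)
            pixels.append(rgb_to_hsv(frame)[mask])
        pooled = np.concatenate(pixels, axis=0)
        for c, ch in enumerate(_CHANNELS):
            values = pooled[:, c]
            hist, _ = np.histogram(values, bins=edges)
            hists[ch][g] = hist / hist.sum()
            means[ch][g] = values.mean()
        times[g] = float(np.mean([frame.time_s for frame, _ in group]))
        counts[g] = len(group)
    return HSVHistogramSeries(time_s=times, hist=hists, means=means,
                              frames_per_window=counts, bin_edges=edges)


def _pooled_moments(series: HSVHistogramSeries, channel: str,
                    idx: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Weighted pooled histogram, mean and SD for a set of windows."""
    weights = series.frames_per_window[idx].astype(float)
    hist = np.average(series.hist[channel][idx], axis=0, weights=weights)
    centres = 0.5 * (series.bin_edges[:-1] + series.bin_edges[1:])
    mean = float(np.average(series.means[channel][idx], weights=weights))
    var = float(np.sum(hist * (centres - np.sum(hist * centres)) ** 2))
    return mean, np.sqrt(var), hist


def shift_metric(series: HSVHistogramSeries,
                 baseline_idx, test_idx) -> dict[str, ChannelShift]:
    """Per-channel distribution shift between two disjoint window sets.

    The standardised effect is the difference of pooled means divided by
    the two groups' pooled standard deviation (0 when both are degenerate
    and identical); the total-variation distance is half the L1 distance
    between the pooled normalised histograms.
    """
    baseline_idx = np.asarray(baseline_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if baseline_idx.size == 0 or test_idx.size == 0:
        raise ValueError("baseline and test window sets must be non-empty")
    if np.intersect1d(baseline_idx, test_idx).size:
        raise ValueError("baseline and test window sets must be disjoint")
    out = {}
    for ch in _CHANNELS:
        mean_b, sd_b, hist_b = _pooled_moments(series, ch, baseline_idx)
        mean_t, sd_t, hist_t = _pooled_moments(series, ch, test_idx)
        diff = mean_t - mean_b
        pooled_sd = float(np.sqrt(0.5 * (sd_b ** 2 + sd_t ** 2)))
        if pooled_sd > 0:
            effect = diff / pooled_sd
        else:
            effect = 0.0 if diff == 0 else float(np.inf) * np.sign(diff)
        tv = 0.5 * float(np.abs(hist_b - hist_t).sum())
        out[ch] = ChannelShift(mean_diff=float(diff), pooled_sd=pooled_sd,
                               effect=float(effect), tv_distance=tv)
    return out
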