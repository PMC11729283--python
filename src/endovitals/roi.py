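"""Per-frame detection of the guiding-catheter lumen as a circle.

Pipeline: take the red channel (best tissue/catheter contrast), binarise
with a Bradley-style local-mean threshold, consolidate with a morphological
closing, extract the external boundary of each large connected component,
fit a circle to each boundary by algebraic (Kasa) least squares and keep
the candidate with the smallest RMS residual whose radius is plausible for
the catheter lumen.  Frames where no plausible circle exists - full-field
blood incursion, uniform fields - come back with ``valid=False`` rather
than raising.

Threshold semantics: a pixel is foreground when its red value exceeds
``m_w(x, y) * 2 * (1 - sensitivity)``, where ``m_w`` is the local mean over
a square window of ``floor(min(H, W) / 8) * 2 + 1`` pixels (mirror-padded
at the borders).  Sensitivity 0.5 is therefore a plain local-mean
threshold and larger values admit more foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import AnalysisError, Frame


@dataclass
class CircleROI:
    """A fitted catheter-lumen circle in pixel coordinates.

    ``residual`` is the root-mean-square distance of the boundary points
    from the fitted circle; invalid circles carry no usable geometry.
    """

    cx: float
    cy: float
    r: float
    residual: float
    valid: bool

    @classmethod
    def invalid(cls) -> "CircleROI":
        return cls(cx=float("nan"), cy=float("nan"), r=float("nan"),
                   residual=float("inf"), valid=False)


@dataclass
class RoiParams:
    """Tunables of the detection chain (defaults follow the method text)."""

    sensitivity: float = 0.6
    disk_diameter_px: int = 3
    shrink: float = 0.9
    max_residual_px: float = 2.0
    r_min_frac: float = 0.15
    r_max_frac: float = 0.49
    min_area_frac: float = 0.01
    window_px: int | None = None  # None -> floor(min(H, W) / 8) * 2 + 1

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity < 1.0:
            raise ValueError("sensitivity must be in (0, 1)")
        if not 0.0 < self.shrink <= 1.0:
            raise ValueError("shrink must be in (0, 1]")
        if not self.r_min_frac < self.r_max_frac:
            raise ValueError("need r_min_frac < r_max_frac")


def _auto_window(shape: tuple[int, int]) -> int:
    return (min(shape) // 8) * 2 + 1


def binarise_red(frame: Frame, sensitivity: float = 0.6,
                 window_px: int | None = None) -> np.ndarray:
    """Adaptive local-mean binarisation of the red channel."""
    red = frame.pixels[:, :, 0].astype(float)
    window = window_px or _auto_window(red.shape)
    local_mean = ndimage.uniform_filter(red, size=window, mode="mirror")
    return red > local_mean * 2.0 * (1.0 - sensitivity)


def _disk_footprint(diameter_px: int) -> np.ndarray:
    radius = diameter_px // 2
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return xx ** 2 + yy ** 2 <= radius ** 2


def close_binary(binary: np.ndarray, disk_diameter_px: int = 3) -> np.ndarray:
    """Morphological closing with a disk structuring element.

    The input is padded with background before dilation so the result is
    always a superset of the input, including at the borders.
    """
    radius = disk_diameter_px // 2
    if radius == 0:
        return binary.copy()
    footprint = _disk_footprint(disk_diameter_px)
    padded = np.pad(binary.astype(bool), radius, mode="constant")
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=footprint),
        structure=footprint)
    return closed[radius:-radius, radius:-radius] | binary.astype(bool)


def fit_circle(points: np.ndarray) -> CircleROI:
    """Algebraic (Kasa) least-squares circle through (x, y) points.

    Exact for points lying on a true circle; returns an invalid circle for
    fewer than 3 points or a collinear set.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        return CircleROI.invalid()
    x, y = pts[:, 0], pts[:, 1]
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 3:
        return CircleROI.invalid()
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r_sq = sol[2] + cx ** 2 + cy ** 2
    if not np.isfinite(r_sq) or r_sq <= 0:
        return CircleROI.invalid()
    r = float(np.sqrt(r_sq))
    dist = np.hypot(x - cx, y - cy)
    residual = float(np.sqrt(np.mean((dist - r) ** 2)))
    return CircleROI(cx=float(cx), cy=float(cy), r=r,
                     residual=residual, valid=True)


def _component_boundaries(closed: np.ndarray, min_area: float):
    """External boundary pixel coordinates of each large component."""
    labels, n = ndimage.label(closed, structure=np.ones((3, 3), dtype=int))
    boundaries = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        if sl is None:
            continue
        mask = labels[sl] == lab
        if mask.sum() < min_area:
            continue
        filled = ndimage.binary_fill_holes(mask)
        interior = ndimage.binary_erosion(filled, border_value=0)
        edge = filled & ~interior
        ys, xs = np.nonzero(edge)
        boundaries.append(np.column_stack([xs + sl[1].start, ys + sl[0].start]))
    return boundaries


def detect_roi(frame: Frame, params: RoiParams | None = None) -> CircleROI:
    """Detect the catheter-lumen circle in one frame.

    Among boundary fits whose radius lies inside
    ``[r_min_frac, r_max_frac] * min(H, W)`` the smallest-residual circle
    wins (ties broken toward the larger radius); ``valid=False`` when no
    candidate passes or the best residual exceeds ``max_residual_px``.
    """
    params = params or RoiParams()
    h, w = frame.shape
    binary = binarise_red(frame, params.sensitivity, params.window_px)
    closed = close_binary(binary, params.disk_diameter_px)
    r_min = params.r_min_frac * min(h, w)
    r_max = params.r_max_frac * min(h, w)
    candidates = []
    for pts in _component_boundaries(closed, params.min_area_frac * h * w):
        circle = fit_circle(pts)
        if circle.valid and r_min <= circle.r <= r_max:
            candidates.append(circle)
    if not candidates:
        return CircleROI.invalid()
    best = min(candidates, key=lambda c: (c.residual, -c.r))
    if best.residual > params.max_residual_px:
        return CircleROI.invalid()
    return best


def roi_mask(circle: CircleROI, shrink: float, height: int,
             width: int) -> np.ndarray:
    """Boolean mask of pixels inside the circle shrunk by ``shrink``.

    The radius is shrunk (90% by default upstream) to exclude boundary
    effects such as blood creeping along the catheter wall.
    """
    if not circle.valid:
        raise AnalysisError("cannot build an ROI mask from an invalid circle")
    yy, xx = np.mgrid[0:height, 0:width]
    return ((xx - circle.cx) ** 2 + (yy - circle.cy) ** 2
            <= (shrink * circle.r) ** 2)
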