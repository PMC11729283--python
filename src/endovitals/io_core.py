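"""File formats and the shared video/spectra data model.

The video carrier is a directory of lexicographically ordered frame images
(``frame_000000.tif`` ...; PNG accepted on read, 16-bit TIFF written) plus a
``meta.json`` sidecar giving at least the frame rate; a single multi-page
TIFF with a sibling JSON sidecar is accepted as an alternative.  Spectra travel as a UTF-8, comma-delimited CSV whose
first column is the wavelength grid in nm and whose remaining columns are
one acquisition each, named either by their acquisition time in seconds or
``dark`` / ``reference``.

All pixel intensities are stored internally as floats in [0, 1]; integer
images are normalised by ``value / (2**bits - 1)`` on read.  Pixel
coordinates are 0-based with x = column, y = row and the origin at the
top-left pixel centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd


class EndoVitalsError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(EndoVitalsError):
    """Missing or inconsistent run configuration (e.g. absent sidecar)."""


class FormatError(EndoVitalsError):
    """A file does not follow the expected on-disk dialect."""


class CalibrationError(EndoVitalsError):
    """Reflectance calibration is impossible on the analysis range."""


class AnalysisError(EndoVitalsError):
    """An analysis operation received unusable input (e.g. no valid frames)."""


MIN_FRAME_SIDE = 16

_SPECIAL_COLUMNS = {"dark", "reference"}


@dataclass
class Frame:
    """One RGB video frame.

    ``pixels`` is an H x W x 3 float array with channels ordered R, G, B and
    intensities in [0, 1]; ``time_s`` is seconds from sequence start.
    """

    pixels: np.ndarray
    index: int
    time_s: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(f"frame {self.index}: expected H x W x 3 pixels, "
                              f"got shape {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < MIN_FRAME_SIDE or w < MIN_FRAME_SIDE:
            raise FormatError(f"frame {self.index}: {h}x{w} is below the "
                              f"minimum size of {MIN_FRAME_SIDE} px")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise FormatError(f"frame {self.index}: intensities outside [0, 1] "
                              f"(min {lo:.4g}, max {hi:.4g})")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class VideoSequence:
    """Ordered RGB frames with a common frame rate and free-form metadata."""

    frames: list[Frame]
    fps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigurationError("fps must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent frame dimensions: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])

    def as_array(self) -> np.ndarray:
        """Stack frames into an (N, H, W, 3) array."""
        return np.stack([f.pixels for f in self.frames])


@dataclass
class SpectrumRecord:
    """One spectrum on a strictly increasing wavelength grid (nm).

    ``kind`` is one of ``raw``, ``dark``, ``reference`` or ``calibrated``;
    calibrated values are dimensionless reflectance and must be >= 0.
    """

    wavelength_nm: np.ndarray
    values: np.ndarray
    time_s: float
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.size < 2:
            raise FormatError("wavelength grid must be a 1-D array of >= 2 samples")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise FormatError("wavelength grid must be strictly increasing")
        if self.values.shape != self.wavelength_nm.shape:
            raise FormatError("values and wavelength grid differ in length")
        if self.kind not in {"raw", "dark", "reference", "calibrated"}:
            raise FormatError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "calibrated" and np.any(self.values < 0):
            raise FormatError("calibrated reflectance must be >= 0")


def _normalise_pixels(img: np.ndarray) -> np.ndarray:
    """Convert an image of any supported dtype to float RGB in [0, 1]."""
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    if np.issubdtype(img.dtype, np.integer):
        scale = float(2 ** (8 * img.dtype.itemsize) - 1)
        return img.astype(np.float32) / scale
    return np.clip(img.astype(np.float32), 0.0, 1.0)


def _load_sidecar(path: Path) -> dict:
    if not path.exists():
        raise ConfigurationError(f"missing JSON sidecar: {path}")
    with open(path, encoding="utf-8") as fh:
        meta = json.load(fh)
    if "fps" not in meta:
        raise ConfigurationError(f"sidecar {path} does not define 'fps'")
    return meta


def read_video(path: str | Path) -> VideoSequence:
    """Read a frame-directory (or multi-page TIFF) plus JSON sidecar.

    Timestamps are assigned as ``index / fps``; the sidecar is carried
    verbatim in ``meta``.
    """
    path = Path(path)
    if path.is_dir():
        meta = _load_sidecar(path / "meta.json")
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise FormatError(f"no frame images found in {path}")
        import tifffile

        images = [tifffile.imread(p) if p.suffix.lower() != ".png"
                  else iio.imread(p) for p in files]
    elif path.suffix.lower() in {".tif", ".tiff"}:
        meta = _load_sidecar(path.with_suffix(".json"))
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == 3 and stack.shape[2] in (3, 4):
            stack = stack[None]
        images = list(stack)
    else:
        raise FormatError(f"unsupported video path: {path}")
    fps = float(meta["fps"])
    frames = [Frame(_normalise_pixels(np.asarray(img)), i, i / fps)
              for i, img in enumerate(images)]
    return VideoSequence(frames=frames, fps=fps, meta=meta)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_video(video: VideoSequence, path: str | Path) -> Path:
    """Write a sequence as 16-bit TIFF frames plus ``meta.json``.

    TIFF is used on the write side for dependable 16-bit RGB support; the
    reader accepts both PNG and TIFF frame directories.
    """
    import tifffile

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for frame in video.frames:
        img = np.round(np.clip(frame.pixels, 0, 1) * 65535).astype(np.uint16)
        tifffile.imwrite(path / f"frame_{frame.index:06d}.tif", img)
    h, w = video.shape
    meta = {"fps": video.fps, "width": w, "height": h,
            "notes": video.meta.get("notes", "")}
    meta.update(_json_safe(video.meta))
    with open(path / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh)
    return path


def read_spectra(path: str | Path) -> list[SpectrumRecord]:
    """Read a spectra CSV into one record per data column.

    Columns named ``dark`` / ``reference`` are returned with the matching
    kind; every other column name must parse as an acquisition time in
    seconds and yields a ``raw`` record.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: spectra CSV needs a wavelength column "
                          "plus at least one data column")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise FormatError(f"{path}: wavelength column is not strictly increasing")
    records: list[SpectrumRecord] = []
    for name in df.columns[1:]:
        key = str(name).strip().lower()
        values = df[name].to_numpy(dtype=float)
        if key in _SPECIAL_COLUMNS:
            records.append(SpectrumRecord(wl, values, time_s=0.0, kind=key))
        else:
            try:
                t = float(key)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: column {name!r} is neither a time nor "
                    "'dark'/'reference'") from exc
            records.append(SpectrumRecord(wl, values, time_s=t, kind="raw"))
    return records


def write_spectra(records: list[SpectrumRecord], path: str | Path) -> Path:
    """Write records sharing one wavelength grid to a spectra CSV."""
    if not records:
        raise FormatError("no spectra to write")
    wl = records[0].wavelength_nm
    for rec in records[1:]:
        if not np.array_equal(rec.wavelength_nm, wl):
            raise FormatError("records do not share a wavelength grid")
    data = {"wavelength_nm": wl}
    for rec in records:
        name = rec.kind if rec.kind in _SPECIAL_COLUMNS else f"{rec.time_s:.6f}"
        data[name] = rec.values
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    return path
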