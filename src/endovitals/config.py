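"""Run configuration: every tunable of every module, YAML round-trippable.

An empty config is valid - each section falls back to the module defaults
- and ``RunConfig.from_yaml(RunConfig().to_yaml(...))`` is lossless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io_core import ConfigurationError
from .ppg import PpgParams
from .roi import RoiParams
from .synthetic import DRSForwardParams, OcclusionProtocol, VideoScene


@dataclass
class DrsAcquisition:
    """Synthetic DRS acquisition: rate (80 ms per spectrum) and duration."""

    rate_hz: float = 12.5
    duration_s: float = 120.0


@dataclass
class HistogramParams:
    """HSV histogram windowing: 20 valid frames per histogram, 64 bins."""

    window_frames: int = 20
    bins: int = 64
    window_seconds: float | None = None


_SECTIONS = {
    "scene": VideoScene,
    "protocol": OcclusionProtocol,
    "forward": DRSForwardParams,
    "drs": DrsAcquisition,
    "roi": RoiParams,
    "ppg": PpgParams,
    "histogram": HistogramParams,
}


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class RunConfig:
    """All tunable parameters of a run, with defaults fixed per module."""

    seed: int = 0
    scene: VideoScene = field(default_factory=VideoScene)
    protocol: OcclusionProtocol = field(default_factory=OcclusionProtocol)
    forward: DRSForwardParams = field(default_factory=DRSForwardParams)
    drs: DrsAcquisition = field(default_factory=DrsAcquisition)
    roi: RoiParams = field(default_factory=RoiParams)
    ppg: PpgParams = field(default_factory=PpgParams)
    histogram: HistogramParams = field(default_factory=HistogramParams)

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        data = dict(data or {})
        kwargs: dict = {}
        if "seed" in data:
            kwargs["seed"] = int(data.pop("seed"))
        for name, section_cls in _SECTIONS.items():
            section = data.pop(name, None)
            if section is None:
                continue
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(section) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in section '{name}': {sorted(unknown)}")
            kwargs[name] = section_cls(**section)
        if data:
            raise ConfigurationError(f"unknown config sections: {sorted(data)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
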