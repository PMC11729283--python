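"""Physics-based synthetic endoscope video and DRS spectra with ground truth.

The generator emulates the two measurement branches of a catheter-based
cardiac endoscope so every analysis stage can be tested without in vivo
recordings:

* **Spectra branch** - time-resolved diffuse reflectance under a modified
  Beer-Lambert forward model, R(lambda) = R_s(lambda) *
  exp(-mu_a(lambda) * L), with a power-law scattering background
  R_s = a * (lambda / 650 nm)^(-b) and an absorption coefficient
  mu_a = ln(10) * c_THb * (so2 * eps_HbO2 + (1 - so2) * eps_Hb).
  Oxygen saturation follows a piecewise-exponential occlusion/reperfusion
  trajectory and the heartbeat rides on the hemoglobin concentration as a
  small multiplicative ripple.

* **Video branch** - a pulsatile tissue disc seen through a dark guiding
  catheter at 40 frames/s.  The tissue colour is obtained by pushing the
  forward-model spectrum through the CIE 1931 colorimetry pipeline, so
  video colour and spectra are mutually consistent; cardiac and
  respiratory modulation, centre jitter, pixel noise and intermittent
  full-field blood-incursion frames are added on top.  Ground truth
  (circle geometry, per-frame flags, modulation waveform, so2) is stored
  in the sequence metadata.

The hemoglobin extinction table used by the forward model is a *synthetic*
analytic stand-in for the standard tabulated compilations: sums of Gaussian
bands placed so that oxyhemoglobin shows its double absorption maxima at
~542/576 nm (rounding to 540/575 at 5 nm), deoxyhemoglobin a single maximum
at ~555 nm, with the blue and near-infrared wings shaped to reproduce the
reported in vivo colour whitening and NIR reflectance increase under
deoxygenation.  See docs/methods.md for the exact band parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import colorimetry
from .io_core import Frame, SpectrumRecord, VideoSequence
from .roi import CircleROI


# --------------------------------------------------------------------------
# chromophores

@dataclass
class ChromophoreTable:
    """Molar extinction (1/(cm M)) of HbO2 and Hb on a wavelength grid."""

    wavelength_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("chromophore grid must be strictly increasing")
        if np.any(self.eps_hbo2 <= 0) or np.any(self.eps_hb <= 0):
            raise ValueError("extinction coefficients must be positive")


def _g(wl: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


def _asym_g(wl: np.ndarray, centre: float, sigma_lo: float,
            sigma_hi: float) -> np.ndarray:
    sigma = np.where(wl < centre, sigma_lo, sigma_hi)
    return np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


@lru_cache(maxsize=4)
def hemoglobin_table(step_nm: float = 2.0) -> ChromophoreTable:
    """Synthetic analytic hemoglobin extinction table, 450-1000 nm.

    Band placement (Q bands at 542/576 nm for HbO2, 556 nm for Hb; Soret
    tails below 460 nm) matches the textbook peak positions; amplitudes and
    wings are the package's own calibration, not a published compilation.
    """
    wl = np.arange(450.0, 1000.0 + 0.5 * step_nm, step_nm)
    # broad backgrounds shared by both species (isosbestic backbone plus a
    # common blue absorber keeping the tissue colour on the red/orange side)
    bg = 2.1e4 * _g(wl, 545.0, 70.0) + 4.5e4 * _g(wl, 440.0, 22.0)
    eps_hbo2 = (bg
                + 3.0e5 * _g(wl, 415.0, 20.0)      # Soret tail
                + 5.3e4 * _g(wl, 542.0, 9.0)       # Q band (alpha)
                + 5.4e4 * _g(wl, 576.0, 9.0)       # Q band (beta)
                + 280.0 + 850.0 / (1.0 + np.exp(-(wl - 760.0) / 50.0)))
    eps_hb = (bg
              + 1.0e5 * _g(wl, 430.0, 15.0)        # Soret tail
              + 2.0e4 * _asym_g(wl, 554.0, 30.0, 11.0)  # single broad Q band
              + 1.2e4 * _g(wl, 600.0, 30.0)        # red shoulder
              + 150.0)
    return ChromophoreTable(wl, eps_hbo2, eps_hb)


# --------------------------------------------------------------------------
# DRS forward model

@dataclass
class DRSForwardParams:
    """Parameters of the modified Beer-Lambert reflectance model.

    c_thb: total hemoglobin concentration (mol/L); so2: oxygen saturation
    fraction; path_cm: effective mean photon path length (cm); scatter_a /
    scatter_b: amplitude and wavelength exponent of the power-law
    scattering background; pulse_amp: fractional heartbeat ripple on
    c_thb; noise_sd: multiplicative Gaussian noise standard deviation.
    """

    c_thb: float = 1.0e-4
    so2: float = 0.97
    path_cm: float = 0.25
    scatter_a: float = 0.7
    scatter_b: float = 1.3
    pulse_amp: float = 0.05
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError("so2 must be in [0, 1]")
        if self.c_thb < 0 or self.path_cm <= 0:
            raise ValueError("need c_thb >= 0 and path_cm > 0")


def absorption_coefficient(params: DRSForwardParams,
                           chromophores: ChromophoreTable,
                           wavelength_nm: np.ndarray,
                           so2: float | None = None,
                           c_thb: float | None = None) -> np.ndarray:
    """mu_a(lambda) = ln(10) * c_THb * (so2 eps_HbO2 + (1-so2) eps_Hb), 1/cm."""
    wl = np.asarray(wavelength_nm, dtype=float)
    table = chromophores
    if wl.min() < table.wavelength_nm[0] or wl.max() > table.wavelength_nm[-1]:
        raise ValueError("wavelength grid outside the chromophore table range "
                         f"[{table.wavelength_nm[0]}, {table.wavelength_nm[-1]}] nm")
    so2 = params.so2 if so2 is None else so2
    c = params.c_thb if c_thb is None else c_thb
    eps_o = np.interp(wl, table.wavelength_nm, table.eps_hbo2)
    eps_d = np.interp(wl, table.wavelength_nm, table.eps_hb)
    return math.log(10.0) * c * (so2 * eps_o + (1.0 - so2) * eps_d)


def drs_reflectance(params: DRSForwardParams,
                    chromophores: ChromophoreTable | None = None,
                    wavelength_nm: np.ndarray | None = None,
                    so2: float | None = None,
                    c_thb: float | None = None,
                    time_s: float = 0.0) -> SpectrumRecord:
    """Noise-free forward reflectance spectrum on the given grid.

    Deterministic; noise and the heartbeat ripple are applied by
    :func:`generate_drs_timeseries`.
    """
    chromophores = chromophores or hemoglobin_table()
    wl = (np.arange(450.0, 1000.0 + 0.5, 1.0)
          if wavelength_nm is None else np.asarray(wavelength_nm, dtype=float))
    mu_a = absorption_coefficient(params, chromophores, wl, so2=so2, c_thb=c_thb)
    scatter = params.scatter_a * (wl / 650.0) ** (-params.scatter_b)
    values = scatter * np.exp(-mu_a * params.path_cm)
    return SpectrumRecord(wl, values, time_s=time_s, kind="calibrated")


# --------------------------------------------------------------------------
# occlusion / reperfusion protocol

@dataclass
class OcclusionProtocol:
    """Balloon occlusion intervals and the saturation relaxation constants.

    Saturation relaxes exponentially toward ``occluded_so2`` (time constant
    ``tau_fall_s``) inside each interval and back toward ``baseline_so2``
    (``tau_rise_s``) outside, continuously.
    """

    baseline_so2: float = 0.97
    occluded_so2: float = 0.20
    intervals: tuple[tuple[float, float], ...] = ()
    tau_fall_s: float = 5.0
    tau_rise_s: float = 5.0

    def __post_init__(self) -> None:
        self.intervals = tuple((float(a), float(b)) for a, b in self.intervals)
        if not 0.0 <= self.occluded_so2 < self.baseline_so2 <= 1.0:
            raise ValueError("need 0 <= occluded_so2 < baseline_so2 <= 1")
        last = -math.inf
        for a, b in self.intervals:
            if not (a < b and a >= last):
                raise ValueError("occlusion intervals must be disjoint and ordered")
            last = b


def so2_at(protocol: OcclusionProtocol, t_s):
    """Saturation fraction at time(s) ``t_s`` under the protocol."""
    t = np.asarray(t_s, dtype=float)
    out = np.full(t.shape, protocol.baseline_so2)
    # walk the piecewise segments, carrying the entry value of each
    edges: list[tuple[float, float, float]] = []  # (start, target, tau)
    prev = 0.0
    for a, b in protocol.intervals:
        edges.append((prev, protocol.baseline_so2, protocol.tau_rise_s))
        edges.append((a, protocol.occluded_so2, protocol.tau_fall_s))
        prev = b
    edges.append((prev, protocol.baseline_so2, protocol.tau_rise_s))
    v0 = protocol.baseline_so2
    for i, (start, target, tau) in enumerate(edges):
        end = edges[i + 1][0] if i + 1 < len(edges) else math.inf
        mask = (t >= start) & (t < end)
        out[mask] = target + (v0 - target) * np.exp(-(t[mask] - start) / tau)
        v0 = target + (v0 - target) * math.exp(-(end - start) / tau) \
            if math.isfinite(end) else target
    return float(out) if np.isscalar(t_s) else out


def generate_drs_timeseries(params: DRSForwardParams,
                            protocol: OcclusionProtocol,
                            duration_s: float,
                            rate_hz: float = 12.5,
                            seed: int | np.random.Generator = 0,
                            hr_bpm: float = 98.0,
                            chromophores: ChromophoreTable | None = None,
                            wavelength_nm: np.ndarray | None = None,
                            ) -> list[SpectrumRecord]:
    """One calibrated spectrum per acquisition tick.

    so2 follows the protocol, the heartbeat multiplies c_thb by
    ``(1 + pulse_amp * sin(2 pi f_c t))`` and multiplicative Gaussian noise
    of standard deviation ``noise_sd`` is applied; reproducible per seed.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    chromophores = chromophores or hemoglobin_table()
    f_c = hr_bpm / 60.0
    n = int(round(duration_s * rate_hz))
    records = []
    for k in range(n):
        t = k / rate_hz
        c_eff = params.c_thb * (1.0 + params.pulse_amp
                                * math.sin(2.0 * math.pi * f_c * t))
        rec = drs_reflectance(params, chromophores, wavelength_nm,
                              so2=so2_at(protocol, t), c_thb=c_eff, time_s=t)
        if params.noise_sd > 0:
            rec.values *= 1.0 + rng.normal(0.0, params.noise_sd, rec.values.size)
            rec.values = np.clip(rec.values, 0.0, None)
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# video scene

@dataclass
class VideoScene:
    """Geometry and modulation parameters of the synthetic endoscope scene.

    The porcine default preset: a 120x120 px field with a centred tissue
    disc of radius 45 px inside a dark guiding catheter, 40 frames/s for
    120 s, heart rate 98 beats/min and respiration 12 breaths/min.
    """

    height: int = 120
    width: int = 120
    cx: float = 60.0
    cy: float = 60.0
    r_cath: float = 45.0
    jitter_sd: float = 0.5
    hr_bpm: float = 98.0
    rr_bpm: float = 12.0
    a_c: float = 0.05   # cardiac modulation depth
    a_r: float = 0.3    # respiratory AM depth on the cardiac component
    a_b: float = 0.02   # respiratory baseline modulation depth
    incursion_prob: float = 0.05
    noise_sd: float = 0.02
    duration_s: float = 120.0
    fps: float = 40.0
    wall_value: float = 0.10
    blood_rgb: tuple[float, float, float] = (0.30, 0.04, 0.05)

    def __post_init__(self) -> None:
        if self.r_cath >= min(self.height, self.width) / 2:
            raise ValueError("catheter radius must fit inside the frame")
        if not 0.0 <= self.incursion_prob <= 1.0:
            raise ValueError("incursion_prob must be in [0, 1]")
        for name in ("a_c", "a_r", "a_b"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


def modulation_waveform(scene: VideoScene, t_s) -> np.ndarray:
    """Combined cardiac + respiratory brightness factor at time(s) t_s."""
    t = np.asarray(t_s, dtype=float)
    f_c = scene.hr_bpm / 60.0
    f_r = scene.rr_bpm / 60.0
    resp = np.sin(2.0 * np.pi * f_r * t)
    card = np.sin(2.0 * np.pi * f_c * t)
    return (1.0 + scene.a_b * resp) * (1.0 + scene.a_c * (1.0 + scene.a_r * resp) * card)


def tissue_rgb(so2: float, t_s: float, scene: VideoScene,
               params: DRSForwardParams,
               chromophores: ChromophoreTable | None = None,
               cmf: colorimetry.CMFTable | None = None) -> np.ndarray:
    """Pseudo-colour of the tissue at time t, via the colorimetry branch.

    The heartbeat/respiratory ripple also rides on the hemoglobin
    concentration (same form as in the spectra branch) so the colour
    saturation, not only the brightness, pulses at the cardiac and
    respiratory frequencies.
    """
    f_c = scene.hr_bpm / 60.0
    f_r = scene.rr_bpm / 60.0
    ripple = (params.pulse_amp * (1.0 + scene.a_r * math.sin(2 * math.pi * f_r * t_s))
              * math.sin(2 * math.pi * f_c * t_s)
              + scene.a_b * math.sin(2 * math.pi * f_r * t_s))
    c_eff = params.c_thb * (1.0 + ripple)
    spec = drs_reflectance(params, chromophores, so2=so2, c_thb=c_eff)
    return colorimetry.spectrum_to_rgb(spec, cmf)


def render_frame(scene: VideoScene, t_s: float, so2: float,
                 rng: np.random.Generator,
                 index: int = 0,
                 params: DRSForwardParams | None = None,
                 chromophores: ChromophoreTable | None = None,
                 cmf: colorimetry.CMFTable | None = None,
                 ) -> tuple[Frame, CircleROI]:
    """Render one tissue-disc frame and its ground-truth circle.

    Pixels inside the (jittered) circle carry the tissue colour scaled by
    the cardiac/respiratory brightness factor; pixels outside carry the
    dark catheter wall.  Additive Gaussian pixel noise is clipped to [0, 1].
    """
    params = params or DRSForwardParams()
    cx = scene.cx + (rng.normal(0.0, scene.jitter_sd) if scene.jitter_sd > 0 else 0.0)
    cy = scene.cy + (rng.normal(0.0, scene.jitter_sd) if scene.jitter_sd > 0 else 0.0)
    base = tissue_rgb(so2, t_s, scene, params, chromophores, cmf)
    factor = float(modulation_waveform(scene, t_s))
    yy, xx = np.mgrid[0:scene.height, 0:scene.width]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= scene.r_cath ** 2
    pixels = np.full((scene.height, scene.width, 3), scene.wall_value,
                     dtype=np.float32)
    pixels[mask] = np.clip(base * factor, 0.0, 1.0).astype(np.float32)
    if scene.noise_sd > 0:
        pixels += rng.normal(0.0, scene.noise_sd, pixels.shape).astype(np.float32)
    pixels = np.clip(pixels, 0.0, 1.0)
    frame = Frame(pixels, index=index, time_s=t_s)
    truth = CircleROI(cx=float(cx), cy=float(cy), r=float(scene.r_cath),
                      residual=0.0, valid=True)
    return frame, truth


def _blood_frame(scene: VideoScene, t_s: float, index: int,
                 rng: np.random.Generator) -> Frame:
    pixels = np.tile(np.asarray(scene.blood_rgb, dtype=np.float32),
                     (scene.height, scene.width, 1))
    if scene.noise_sd > 0:
        pixels += rng.normal(0.0, scene.noise_sd, pixels.shape).astype(np.float32)
    return Frame(np.clip(pixels, 0.0, 1.0), index=index, time_s=t_s)


def generate_video(scene: VideoScene,
                   protocol: OcclusionProtocol | None = None,
                   seed: int = 0,
                   params: DRSForwardParams | None = None,
                   chromophores: ChromophoreTable | None = None,
                   cmf: colorimetry.CMFTable | None = None) -> VideoSequence:
    """Full synthetic sequence with per-frame ground truth in ``meta``.

    Each frame is independently replaced, with probability
    ``incursion_prob``, by a full-field dark-red blood frame carrying no
    catheter circle.  ``meta`` stores the ground-truth circle per frame,
    the blood flags, the so2 trajectory and the modulation waveform.
    """
    params = params or DRSForwardParams()
    chromophores = chromophores or hemoglobin_table()
    cmf = cmf or colorimetry.cie_1931_table()
    ss = np.random.SeedSequence(seed)
    rng_frames, rng_incursion = (np.random.default_rng(s) for s in ss.spawn(2))
    n = int(round(scene.duration_s * scene.fps))
    blood = rng_incursion.random(n) < scene.incursion_prob
    frames: list[Frame] = []
    circles: list[dict] = []
    so2s = np.empty(n)
    for i in range(n):
        t = i / scene.fps
        so2s[i] = so2_at(protocol, t) if protocol is not None else 0.97
        if blood[i]:
            frames.append(_blood_frame(scene, t, i, rng_frames))
            circles.append({"valid": False, "cx": None, "cy": None, "r": None})
        else:
            frame, truth = render_frame(scene, t, so2s[i], rng_frames, index=i,
                                        params=params,
                                        chromophores=chromophores, cmf=cmf)
            frames.append(frame)
            circles.append({"valid": True, "cx": truth.cx, "cy": truth.cy,
                            "r": truth.r})
    times = np.arange(n) / scene.fps
    meta = {
        "fps": scene.fps,
        "notes": "synthetic endoscope sequence",
        "ground_truth": {
            "hr_bpm": scene.hr_bpm,
            "rr_bpm": scene.rr_bpm,
            "blood": blood.tolist(),
            "circles": circles,
            "so2": so2s.tolist(),
            "modulation": modulation_waveform(scene, times).tolist(),
        },
    }
    return VideoSequence(frames=frames, fps=scene.fps, meta=meta)
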