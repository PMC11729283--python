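# Methods

This note documents the models, defaults and numerical choices behind
`endovitals`, and what the synthetic generator does and does not emulate.

## DRS forward model

Calibrated diffuse reflectance is modelled as modified Beer–Lambert:

    R(λ) = R_s(λ) · exp(−μ_a(λ) · L)
    R_s(λ) = a · (λ / 650 nm)^(−b)
    μ_a(λ) = ln(10) · c_THb · [ s · ε_HbO2(λ) + (1 − s) · ε_Hb(λ) ]

with `s` the oxygen saturation, `c_THb` the effective total hemoglobin
concentration, and `L` an effective mean photon path length. This is the
simplest model that reproduces the qualitative spectral features of
perfused cardiac tissue (the oxyhemoglobin double dip, the single
deoxyhemoglobin dip, the near-infrared reflectance increase under
deoxygenation); diffusion-theory or Monte-Carlo light transport is out of
scope.

Defaults (`DRSForwardParams`): `c_thb = 1.0e-4 mol/L`, `path_cm = 0.25`,
`scatter_a = 0.7`, `scatter_b = 1.3`, heartbeat ripple `pulse_amp = 0.05`
(multiplicative on `c_THb`), multiplicative spectral noise
`noise_sd = 0.01`. The concentration–path product was fixed once so that
the forward spectra show deep, well-separated hemoglobin bands and a
clearly red tissue colour; it is an effective parameter, not a literal
tissue concentration.

### Synthetic hemoglobin extinction table

The extinction curves in `synthetic.hemoglobin_table` are a **synthetic
analytic stand-in** for the standard tabulated compilations: sums of
Gaussian bands on a 2 nm grid over 450–1000 nm. Band positions follow the
textbook values — HbO2 maxima at 542 and 576 nm (rounding to 540/575 at
5 nm granularity), a single Hb maximum near 554–556 nm, Soret tails below
460 nm — and both species share a broad isosbestic backbone plus a common
blue absorber. Two regions are deliberately shaped to reproduce the
reported in vivo behaviour of occluded tissue rather than to match
published extinction tables:

* in 700–900 nm, ε_Hb is kept below ε_HbO2 everywhere, so deoxygenated
  spectra show the higher NIR reflectance observed in vivo (real
  compilations put ε_Hb above ε_HbO2 over part of 700–800 nm);
* the blue wing and the red shoulder of Hb are balanced so the fully
  deoxygenated pseudo-colour is a paler, less saturated red than the
  oxygenated one (in real tissue that whitening also involves
  blood-volume and scattering changes, which this single-parameter model
  does not carry).

Anything that depends quantitatively on real extinction values (e.g.
absolute concentration inversion) is therefore outside what this
generator can validate.

## Occlusion / reperfusion trajectory

Saturation relaxes piecewise-exponentially: toward `occluded_so2` with
time constant `tau_fall_s` inside each occlusion interval and back toward
`baseline_so2` with `tau_rise_s` outside, continuous at every boundary.
Defaults: baseline 0.97, occluded 0.20, both time constants 5 s — so the
ratio recovers to its baseline band in roughly 3τ = 15 s after
reperfusion, consistent with the 10–20 s recovery seen in vivo.

## Video scene

The porcine default preset (`VideoScene`): 120×120 px frames at 40
frames/s for 120 s; a centred tissue disc of radius 45 px inside a dark
catheter wall (value 0.10); heart rate 98 BPM with modulation depth
`a_c = 0.05`; respiration 12 BPM acting both as an amplitude modulation
of the cardiac component (`a_r = 0.3`) and as a baseline brightness
ripple (`a_b = 0.02`); per-frame centre jitter σ = 0.5 px; additive pixel
noise σ = 0.02; 5 % of frames replaced by full-field dark-red blood
frames. The frame size keeps tests fast while leaving the circle fit
over-determined by a few hundred boundary pixels.

The tissue colour of each frame is obtained by pushing the forward-model
spectrum at the current saturation through the CIE 1931 pipeline, so the
video and spectra branches are mutually consistent. The
cardiac/respiratory ripple enters twice, deliberately: as the specified
multiplicative brightness factor, and as a ripple on the hemoglobin
concentration used for the colour. The second path is what gives the
saturation channel genuine cardiac/respiratory content — a pure scalar
brightness factor would leave hue and saturation exactly constant, which
no real pulsatile tissue does.

Ground truth (per-frame circle, blood flags, saturation, modulation
waveform) travels in the sequence metadata. One seed feeds two
independent spawned random streams (frames, incursions), making
generation bit-reproducible.

What the generator does **not** emulate: cardiac wall motion and
deformation, specular highlights, laser speckle, illumination
non-uniformity, optical aberrations, and any spatial structure inside the
tissue disc. Passing tests therefore demonstrate the correctness of the
analysis chain under ideal stabilised-catheter conditions, not robustness
to the full variability of in vivo video.

## ROI detection

"Sensitivity" is given Bradley-style local-mean semantics: foreground is
`red > m_w · 2 · (1 − sensitivity)` with `m_w` the mirror-padded local
mean over a square window of `floor(min(H, W)/8)·2 + 1` px. Sensitivity
0.5 is a plain local-mean threshold; the default 0.6 admits more
foreground. Note that a perfectly uniform region always binarises as
foreground under any pure local-mean rule; such frames are rejected
downstream because their component boundaries fit a circle badly. The
closing uses a disk structuring element of 3 px diameter on a
background-padded domain (so it is always extensive). Candidate
boundaries are the external contours (hole-filled, 8-connected) of
components covering ≥ 1 % of the frame; each is fitted with the algebraic
Kåsa least-squares circle, exact on noiseless circles. Among candidates
with radius in `[0.15, 0.49]·min(H, W)` the smallest RMS residual wins,
ties toward the larger radius; `max_residual_px = 2.0` rejects everything
else (blood frames, uniform frames, border artefacts). The analysis mask
shrinks the fitted radius by 0.9 to avoid boundary effects.

## PPG processing

Invalid frames are linearly interpolated (edges held) before any
spectral step; the series is detrended by subtracting a centred moving
average (default window 10 s, shrinking at the edges) and its residual
mean. The amplitude spectrum is the magnitude of the Hann-windowed DFT,
normalised to a maximum of 1 (identically zero series bypass
normalisation). Band peaks use parabolic interpolation around the argmax
bin; a peak counts only if it is a local maximum and exceeds 4× the
median magnitude within its band — below that the rate is reported as
undefined rather than guessed. Default bands: cardiac 40–200 BPM,
respiratory 5–30 BPM; headline channel V (largest modulation), with S
carrying the same frequencies through the concentration ripple. The
envelope operation is the magnitude of the analytic (Hilbert) signal
smoothed over about one cardiac period (0.6 s default).

## Colorimetry

The CIE 1931 2° observer is represented by the standard piecewise
(two-sided) Gaussian analytic fit — three lobes for x̄, two each for ȳ
and z̄, accurate to about 1 % of peak — on a 5 nm grid, with D65 embedded
as a 10 nm tabulation and interpolated. Tristimulus integration weights
the reflectance by D65 and normalises so a perfect reflector has Y = 1
exactly. XYZ → sRGB uses the standard linear primaries matrix,
white-balanced channel-wise to the embedded illuminant (so the white
point maps to RGB (1,1,1) exactly regardless of the tables'
approximation error), followed by sRGB gamma and clipping; out-of-gamut
colours are clipped after gamma.

Band means are inclusive over centre ± 2.5 nm. Pseudo-colours in the
ratio time series come from 1 s spectral averages (removing the heartbeat
ripple); 3 s averages are the convention for rendering single
representative spectra. The ratio smoothing default is a 31-sample
centred moving average (~2.5 s at the 12.5 Hz acquisition rate set by the
80 ms spectrometer integration), enough to suppress the cardiac ripple.

## HSV histograms

Windows hold 20 **valid** frames by default (invalid frames are skipped,
not counted); a time-based window (`window_seconds`) is available as an
alternative since both conventions are in use. Histograms use 64 uniform
bins on [0, 1] per channel and are normalised per window. The shift
metric compares pooled baseline and test windows per channel: difference
of pooled means, pooled standard deviation (from the pooled histograms),
their ratio as a standardised effect, and the total-variation distance.
No hypothesis test is attached — the metric is descriptive.

## Problem sizes and determinism

All stochastic defaults above *are* the study conditions; tests and the
acceptance script run them unchanged except for duration: the
vital-sign recovery check uses the full 120 s sequence, while the 27-run
parameter-recovery grid (heart rate × respiration × 3 seeds) uses 60 s
sequences, whose 1 BPM spectral bin is the stated recovery tolerance.
Every random quantity flows from a single integer seed through spawned
`numpy` generator streams, so all results in the README and the
acceptance output are bit-reproducible per seed.

## Known limitations

* The forward model has one free physiological axis (saturation, plus a
  concentration ripple); blood-volume, scattering and water/lipid
  changes are not modelled.
* The extinction table is synthetic (see above); wavelengths and
  orderings are meaningful, absolute extinction magnitudes are not.
* ROI detection assumes a roughly circular, roughly centred lumen; no
  ellipse fitting for oblique views and no temporal tracking.
* The PPG branch estimates rates, not SpO2 or perfusion maps.
* Colorimetry is not calibrated against a physical display; pseudo-colour
  differences are qualitative indicators.
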