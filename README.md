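# endovitals

Analysis chain for catheter-based cardiac endoscopy: extract vital signs
and tissue-oxygenation state from (a) camera-on-tip endoscope video and
(b) diffuse reflectance spectroscopy (DRS) of the same tissue.

A miniature camera operated inside a guiding catheter, held against the
cardiac wall with saline flush, sees a disc of tissue surrounded by the
dark catheter wall. The back-scattered intensity of that disc pulses with
blood volume, so a stabilised region of interest (ROI) yields an imaging
photoplethysmogram (PPG) carrying the heart and respiration rates. A
fibre-based DRS probe on the same tissue resolves the hemoglobin
absorption bands and therefore tracks ischemia and reperfusion.

`endovitals` implements, as a tested reusable library plus CLI:

* **ROI detection** — per frame: adaptive (local-mean) binarisation of
  the red channel, morphological closing with a 3 px disk, external
  contours of large components, algebraic (Kåsa) least-squares circle
  fits; the smallest-residual plausible circle wins and frames with no
  plausible circle (blood incursion into the catheter) are flagged
  invalid. The working ROI is the fitted circle shrunk to 90 % of its
  radius.
* **PPG vital signs** — ROI-mean H, S, V per frame; gap interpolation
  over invalid frames; moving-average detrend; Hann-windowed amplitude
  spectrum normalised to 1; heart rate = parabolic-interpolated argmax in
  40–200 BPM, respiration in 5–30 BPM.
* **DRS ratiometry** — reflectance calibration R = (S−D)/(Ref−D) and the
  oxygenation ratio

  ```
  ratio = R(555) / (R(540) + R(575))        (5 nm band means)
  ```

  i.e. the deoxyhemoglobin absorption band over the sum of the two
  oxyhemoglobin bands: higher when the tissue is perfused, lower under
  occlusion.
* **CIE 1931 pseudo-colour** — a full spectrum is collapsed to one colour
  by integrating against the 2° observer colour-matching functions under
  D65 and converting XYZ → sRGB, plus a configurable red/amber/green
  "traffic-light" mapping of the ratio.
* **HSV histogram tracking** — windowed, normalised ROI histograms per
  HSV channel and a baseline-vs-test shift metric (mean difference,
  standardised effect, total-variation distance); the ischemia-induced
  shift appears most strongly in the saturation channel.
* **Synthetic generator** — a physics-based stand-in for in vivo
  recordings: modified Beer–Lambert reflectance over a synthetic
  hemoglobin extinction table, an exponential occlusion/reperfusion
  saturation trajectory, and a rendered pulsatile tissue disc (40 fps,
  jitter, pixel noise, intermittent full-field blood frames) whose colour
  is derived from the same forward model, with full ground truth in the
  metadata.

## Worked example

```python
import numpy as np
from endovitals import (VideoScene, OcclusionProtocol, DRSForwardParams,
                        generate_video, generate_drs_timeseries,
                        detect_roi, extract_ppg, estimate_vitals,
                        ratio_timeseries)

scene = VideoScene(duration_s=60.0)           # porcine preset, 1 min
video = generate_video(scene, seed=1)
circles = [detect_roi(frame) for frame in video.frames]
ppg = extract_ppg(video, circles)
vitals = estimate_vitals(ppg)
print(f"valid frames : {int(ppg.valid.sum())}/{len(video)}")
print(f"heart rate   : {vitals.hr_bpm:.1f} BPM (peak height {vitals.hr_peak_height:.2f})")
print(f"respiration  : {vitals.rr_bpm:.1f} BPM (peak height {vitals.rr_peak_height:.2f})")

protocol = OcclusionProtocol(intervals=((40.0, 80.0),))
records = generate_drs_timeseries(DRSForwardParams(), protocol,
                                  duration_s=120.0, rate_hz=12.5, seed=1)
series = ratio_timeseries(records)
t = series.time_s
base = series.smoothed[(t > 15) & (t < 38)].mean()
occl = series.smoothed[(t > 65) & (t < 78)].mean()
print(f"ratio baseline : {base:.3f}")
print(f"ratio occluded : {occl:.3f}")
```

prints

```
valid frames : 2290/2400
heart rate   : 98.0 BPM (peak height 1.00)
respiration  : 12.0 BPM (peak height 0.40)
ratio baseline : 2.447
ratio occluded : 0.462
```

The 110 rejected frames are the simulated blood incursions (5 % of
frames); the recovered rates equal the generator's ground truth (98 BPM
cardiac, 12 BPM respiratory); and the smoothed reflectance ratio drops
well below baseline while the occlusion is active, recovering within
seconds of reperfusion.

The same pipelines are available from the shell:

```sh
endovitals simulate      --seed 1 --out run/          # frames + spectra CSV
endovitals analyze-video --video run/frames --histograms --seed 1 --out run/video/
endovitals analyze-drs   --spectra run/spectra.csv    --seed 1 --out run/drs/
endovitals report        --ratio run/drs/ratio.csv    --seed 1 --out run/drs/
```

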