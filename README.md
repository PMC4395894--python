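# corvispy

Analysis of air-puff tonometry image sequences from an ultra-fast Scheimpflug
camera (Corvis-type devices). During an intraocular-pressure measurement the
instrument records a cross-sectional movie of the cornea — typically 140
frames of 200 × 576 pixels, one frame every 231 µs — while an air pulse
pushes the cornea inward through two applanation events and a point of
highest concavity. The device's own software reports only a handful of
numbers; this package re-derives the full deformation history from the raw
images and extracts the biomechanical parameters that clinicians and
biomechanics researchers use to characterise the cornea (applanation times,
lengths and velocities, highest-concavity geometry, corneal vs whole-eye
motion, high-frequency corneal vibrations, left/right asymmetry).

## Method

For every frame, each image column is scanned for its largest brightness
gradient: the first rising (dark→bright) gradient peak marks the outer
corneal edge, the strongest falling peak below it the inner edge. Integer
peaks are refined to sub-pixel positions by parabolic interpolation and
repaired per frame by a running-median outlier test. Writing the outer edge
as a surface `y(t, x)` (row index, increasing into the eye), the analysis
decomposes the displacement relative to the pre-puff baseline into

```
y(t, x) − baseline(x) = full(t, x)
full = eyeball + cornea          (eyeball: per-frame linear field anchored
                                  at the scleral margins — rigid retraction
                                  plus tilt)
cornea = cornea_low + vibration  (vibration: temporal FFT bins ≥ 100 Hz,
                                  zero-phase, exactly invertible)
```

Both splits are exact by construction. A single-sided FFT amplitude map of
the corneal deformation per column gives the vibration spectrum; the "first
harmonic" is its dominant sustained line above 100 Hz. All parameters are
reported in pixel/frame units and converted to mm/ms with the calibration
constants (0.15 mm/pixel, 231 µs/frame by default).

A synthetic scene generator renders the whole process — circular-arc
baseline, Gaussian air-puff indentation with raised-cosine timing, eyeball
retraction with tilt, sinusoidal vibration, optical blur and sensor noise —
with exact ground truth, so every stage is testable without patient data.

## Worked example

```python
from corvispy import analyze_sequence, make_paper_like_config, render_sequence

cfg = make_paper_like_config(seed=1)      # clinical-ballpark synthetic scene
seq, truth = render_sequence(cfg)         # 140 frames, 200 x 576 px
result = analyze_sequence(seq)
r = result.report
print(r.applanation1_time_frames, r.applanation2_time_frames)  # 29 96
print(round(r.max_cornea_deformation_px, 2))                   # 66.65
print(round(r.first_harmonic_hz, 1), round(r.first_harmonic_amplitude_px, 3))
#                                                              # 309.2 0.203
```

The scene deforms the cornea by 66.6 px at the apex with a 0.2 px vibration
at 309 Hz; the pipeline recovers the applanation frames exactly, the peak
corneal deformation to within 0.06 px and the vibration line to within one
FFT bin (fs/N ≈ 30.9 Hz) and a few percent in amplitude. Converted with the
default calibration, frames 29 and 96 correspond to 6.7 ms and 22.2 ms, and
66.6 px to 10 mm.

The same workflow is available from the shell:

```
corvispy simulate -o scene --seed 1       # write PNG frames + ground truth
corvispy analyze scene -o results         # report.json/.csv, component maps
corvispy convert 96 --axis temporal       # 22.2 ms
corvispy filter scene --mask 5 -o results_filtered
```

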