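# Methods

## Imaging model and coordinates

A recording is a stack of grayscale cross-sectional frames `[t][row][col]`,
row 0 at the top, rows increasing toward the retina. The cornea appears as a
bright band on a dark background; its outer (anterior) edge lies above its
inner (posterior) edge. Default calibration: 231 µs per frame and
0.15 mm per pixel, both overridable everywhere and never hard-coded in a
computation path. Sub-pixel positions follow the sample convention that an
ideal step between samples `r` and `r+1` is located at `r + 0.5`; the
synthetic renderer integrates band coverage over `[r − 0.5, r + 0.5)` so its
ground truth lives in the same coordinates.

## Contour detection

Per column, the intensity profile is smoothed with a 3-tap binomial kernel
and differentiated by central differences. The outer edge is the first
rising-gradient local maximum from the top whose magnitude reaches
`min_gradient` (default 8 grey levels/px); the inner edge is the strongest
falling peak within `(outer, outer + max_thickness_px]`
(`max_thickness_px = 40`). Equal-gradient ties resolve to the smallest row.
The integer peak is refined by parabolic interpolation through the gradient
sample and its two neighbours, clamped to ±0.5 px. Light smoothing
stabilises the argmax under sensor noise without biasing a symmetric edge;
on Gaussian-blurred step edges (σ = 1.5 px) the estimator is accurate to
better than 0.05 px, and the 0.3 px test tolerance is deliberately loose.

Per frame, columns deviating from a running median (window 7) by more than
`jump_tol_px = 6` are re-flagged invalid; invalid runs are filled by linear
interpolation between nearest valid neighbours (nearest-value extension at
the borders). A frame with more than half its columns undetectable fails
outright; up to `max_failed_frames = 5` such frames are interpolated in
time, more abort the analysis. Polynomial smoothing of the contour is
deliberately not used: low-order fits can hallucinate contour sections that
are not in the image.

## Deformation decomposition

* **Baseline**: mean outer contour over the first `baseline_frames = 10`
  frames (pre-puff). The pulse envelope in the synthetic scenes is zero over
  this window by construction.
* **Full deformation**: `outer − baseline`, positive inward.
* **Eyeball response**: per frame, a linear-in-column field anchored so its
  mean over each scleral margin (`scleral_margin = 50` columns per side)
  equals the observed margin mean; the anchors sit at the margin centroids.
  A scalar per frame cannot represent the tilt visible in real recordings;
  a linear field is the simplest model consistent with rigid retraction plus
  tilt and it yields the left/right asymmetry parameters directly.
* **Cornea**: `full − eyeball`, exact.
* **Vibration**: per column, the inverse FFT of the corneal-deformation
  spectrum with all bins below `cutoff_hz = 100` (including DC) zeroed.
  Zero-phase and exactly invertible: `cornea_low = cornea − vibration`
  holds to machine precision and the vibration has no energy below the
  cutoff. No temporal window is applied (N = 140 is short; a window would
  bias amplitude recovery), so spectral leakage of transients is part of the
  tested contract rather than hidden.

Median filtering (masks none/3/5/9/11/23, edge replication) is applied to
the full-deformation map before the split when requested; all downstream
parameters are recomputed from the filtered map.

## Spectral analysis and the first harmonic

The spectral map is the single-sided FFT amplitude of the corneal
deformation per column: `(2/N)|X_k|` at interior bins, `(1/N)|X_k|` at DC
and Nyquist, so a bin-centred sinusoid of amplitude *a* reads *a* and
Parseval's identity holds against the time-domain energy.

The air-puff indentation is a large transient (tens of px over ~90 frames)
whose spectrum genuinely extends past 100 Hz: for the default scene its
skirt reaches ≈1.4 px at 123.7 Hz and ≈0.2 px at 216 Hz — the same order as
the >100 Hz deformation map itself, which peaks near 2 px. A plain argmax
above 100 Hz therefore finds the skirt, not a sub-pixel vibration line. The
first-harmonic search instead weights candidate bins with a raised cosine
rising from 0 at `min_freq_hz = 100` to 1 at `min_freq_hz + 180` Hz and
reports the *unweighted* amplitude of the winning bin. Lines above ≈280 Hz
are selected and reported without bias; lines inside the transition band are
penalised in selection and may be missed when weaker than the transient
skirt — a documented limitation, not a tuning knob. At the highest-curvature
crest columns the reported harmonic amplitude is the spectral amplitude of
the sequence-wide first-harmonic bin at that column.

## Biomechanical parameters

* **Applanation 1/2**: per frame, the apex-centred window
  (`applanation_halfwidth = 100` columns) is searched for a run of at least
  `min_applanation_len_px = 60` consecutive columns whose outer contour
  deviates less than `flatness_tol_px = 0.4` from the run's own
  least-squares line. Applanation 1 is the first such frame up to highest
  concavity; applanation 2 the first after it. Event length is the longest
  flat run (bisection over run length), velocity the central-difference apex
  displacement rate. These thresholds are pixel-domain defaults pinned by
  the tests; the underlying method publishes no values.
* **Highest concavity**: frame and column of maximal corneal deformation;
  peak distance is the column gap between the two highest contour points
  (local row minima, `scipy.signal.find_peaks` with prominence 0.5) flanking
  the apex; the radius is an algebraic (Kasa) least-squares circle fit
  through the contour between the peaks, flagged infinite for collinear
  segments. Geometric refinement of the fit is out of scope.
* **Amplitudes**: maxima of the full, corneal and per-frame-mean eyeball
  fields; min/max frame-to-frame corneal difference; the "absolute corneal
  reaction" is interpreted as max |cornea| (the name is used in the field
  without a published definition).
* **Corneal length change**: polyline arc length of the outer contour per
  frame minus the baseline's, over a configurable span (default full width).
* **Ratios**: max corneal deformation over max arc-length change, and over
  the baseline apex row position. Both denominators are
  implementation-defined conventions and flagged as such in the report.
* **Vibration metrics**: max |vibration|, and the number of frames whose
  per-column analytic-signal (Hilbert) envelope exceeds
  `vibration_threshold_px = 0.1`; the envelope avoids undercounting at
  carrier zero crossings.
* **Asymmetry / eye side**: the signed left-minus-right scleral anchor
  difference at the frame of its largest magnitude (so mirroring the image
  negates it exactly); |score| ≤ 0.5 px reads "undetermined". Which
  anatomical side corresponds to a positive score is a convention of this
  package, not a device property.
* **Pachymetry**: baseline inner-minus-outer contour gap at the apex column
  — a contour thickness in pixels, not the device's optical pachymetry.
* **Unit conversion**: spatial px → mm and temporal frames → ms by the two
  calibration constants, rounded half away from zero at the requested
  precision.

## Synthetic scenes

The generator emulates: a circular-arc baseline (default radius 450 px, apex
row 30), constant corneal thickness (15 px), a central inward Gaussian bump
(66.6 px × σ 45 px) with a raised-cosine temporal envelope, an eyeball
response with distinct left/right amplitudes (29/19 px) and its own
raised-cosine timing, a sinusoidal vibration (309 Hz, 0.2 px, Gaussian
spatial profile) and additive Gaussian noise (σ 2 grey levels) after a 1 px
optical row blur. Band edges are anti-aliased by exact pixel coverage, which
is what makes sub-pixel contour tolerances meaningful. The ground truth
satisfies `outer = baseline + eyeball + cornea + vibration` exactly and
includes the event schedule computed by applying the same flat-run rule as
the analysis to the noiseless analytic contour.

`make_paper_like_config()` solves the bump envelope onset and offset by
bisection so the flat-run criterion first triggers at frames 29 (inward) and
96 (outward), the timing of a typical clinical case; amplitude, vibration
and eyeball magnitudes mirror the same case. The arc radius and bump width
were chosen once so that the flat-run criterion is attainable between a
curved baseline and a strongly concave peak (flat band roughly 2–17 px of
apex amplitude for this geometry).

What the generator does **not** model: Scheimpflug optical distortion, iris
or lens structures, speckle or multiplicative noise, eye blinks and tear-film
artefacts, or spatially varying corneal thickness. Passing tests demonstrate
correct recovery of the modelled effects at realistic magnitudes, not
robustness to every clinical artefact.

## Numerical choices and degenerate inputs

Gradient ties resolve to the smallest row; parabolic refinement is clamped
to ±0.5 px and falls back to the integer peak when the curvature is zero. A
constant frame equalizes to a single grey level. A statically flat contour
applanates at frame 0 with zero velocity; a rigidly translating curved
contour never applanates; a straight central segment yields an infinite
radius flag rather than an error. Zero deformation yields zero ratios; a
vanishing denominator with non-zero deformation yields an undefined (None)
ratio. Caches are keyed to the source, calibration and detection parameters;
a stale cache triggers recomputation with a warning rather than an error.

## Problem sizes

Tests run on reduced scenes (40–60 frames, 80–200 px wide) where the
property under test allows it; the end-to-end recovery and the acceptance
script use the full 140 × 200 × 576 geometry. The acceptance script's
randomized checks use 20 scenes, matching the suite.
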