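# Methods

## Problem setting

A facial video carries a remote photoplethysmogram (rPPG): the cardiac
blood-volume pulse modulates skin color by a fraction of one 8-bit
quantization step, and averaging over a few thousand skin pixels resolves it
well enough to read heart rate — a privacy leak for any published face video.
`pulseveil` applies lightweight per-frame edits to the skin region that
destroy this signal, and quantifies the trade-off between how much the edit
degrades heart-rate estimation (good) and how much it damages the frames
(bad).

## The modification pipeline

Each frame passes through three steps: extract a region-of-interest mask,
modify the region, overlay the edited region on the original frame. ROIs are
the full frame, the facial skin (convex hull of all landmarks minus the eye
and mouth polygon hulls), or the forehead+cheek patches (union of three
convex hulls). Rasterization is fixed: a pixel (row i, col j) belongs to a
polygon iff its center (j+0.5, i+0.5) lies inside or on the hull boundary;
this makes masks bit-reproducible and testable against an independent
point-in-polygon oracle.

Twelve methods are implemented: NE (identity baseline), median / Gaussian /
bilateral blur, cumulative and sliding temporal averaging, and six noise
injections. Defaults: kernel size 5 for MB/GB; σ_space = σ_range = 75 for the
bilateral filter; 20-frame sliding window for TA-S; unit-scale Gaussian
variance 0.01 (AGN, speckle), hit fraction 0.05 with salt ratio 0.5 (SPN,
pepper), Poisson scale 256, and a 3×3 local sample variance floored at 1e-6
for AGN-L. All noise acts on unit-scaled intensities of the masked pixels,
clips to [0, 1], and rescales.

Temporal averaging is the interesting operator: a length-f moving average is
a comb filter with amplitude gain

    G(fr) = |sin(π·fr·f/r)| / (f·|sin(π·fr/r)|)

at frequency `fr` and frame rate `r`. At f = 20, r = 25 fps the gain is 0.042
at 72 bpm and 0.157 at 90 bpm — the pulse is pushed below the quantization
floor while each frame stays visually sharp. The package verifies measured
gains against this closed form on synthetic sinusoidal pixels.

Numerical conventions (fixed for cross-platform bit-exactness): spatial
borders use reflect-101 padding; accumulation in float64 with
round-half-away-from-zero at the 8-bit boundary; every stochastic method
draws from a `numpy` Generator seeded from its `FilterConfig`.

The bilateral aperture is derived from σ_space (1.5 σ radius) but capped at
15 px by default: at σ_space = 75 the spatial Gaussian is essentially flat
over any practical window, so the range term dominates and the cap changes
results negligibly while keeping the cost linear in window area. The cap is
configurable. Masked blurs are computed on the full frame and then overlaid,
so pixels just inside the ROI border see context from outside it; this
matches the pipeline's overlay semantics and is cheaper than masked-
normalized convolution.

TA-S warm-up averages over the frames available (fewer than f at the start)
rather than emitting unmodified frames, so output is defined and partially
concealed from frame 0.

## The rPPG measurement stack

RGB traces are patch means over up to 100 equispaced forehead/cheek/nose
landmarks (9×9 px patches at the default 128 px scene scale). The trace is
cut into 8-s windows at 1-s stride; each window is linearly detrended and
bandpassed with a zero-phase sixth-order Butterworth filter, 0.65–4.0 Hz
(39–240 bpm). Five classical BVP extractors follow:

* **GREEN** — the green channel.
* **ICA** — seeded FastICA (deflation); components are ranked by in-band
  spectral peakedness (tallest in-band Welch bin over total power) and the
  top one returned. ICA's output order is arbitrary, so the classical
  "pulse component" needs a deterministic selection rule; peakedness picks
  the periodic component and rejects both broadband noise and multi-tone
  illumination flicker, which an in-band *energy* criterion would not.
* **CHROM** — X = 3Rn − 2Gn, Y = 1.5Rn + Gn − 1.5Bn on mean-normalized
  channels, combined as X − (σX/σY)·Y. Normalization divides the bandpassed
  rows by the *raw* window means (the mean of a zero-mean signal is useless),
  giving exact invariance to global intensity scaling.
* **POS** — projection rows (0, 1, −1) and (−2, 1, 1) applied to
  mean-normalized channels, recombined with the adaptive σ ratio. Exactly
  cancels common-mode (equal-relative) intensity fluctuations.
* **LGI** — SVD of the 3×L window; the projector I − u₁u₁ᵀ removes the
  dominant direction and the second row of the projected signal is the BVP.
  Note the structural consequence: on a signal whose only variation is the
  pulse, u₁ *is* the pulse direction and LGI annihilates it — the method
  presumes a stronger common-mode disturbance to project out.

Heart rate is the argmax of the Welch power spectrum (Hann, segments of
min(L, 256) samples, 50 % overlap, zero-padded to a ≤ 0.25 bpm grid)
restricted to the 0.65–4.0 Hz band. Ground-truth series from a contact PPG
use the identical windowing/bandpass/peak path, so video-vs-truth
comparisons carry no estimator asymmetry.

## Scoring

|Δbpm| is the mean absolute per-window difference between ground-truth and
estimated heart rate. MSE is the mean squared pixel difference per frame,
averaged over frames; the squared sum is divided by m·n·3 (channel-averaged;
a per-channel-sum option exists, and MSE is computed on the full frame by
default). The overall score normalizes both across the method set under
comparison:

    OS = ( |Δbpm|_n + (1 − MSE_n) ) / 2

with min-max normalization and |Δbpm| first averaged across rPPG techniques.
OS is a *relative* ranking: it depends on the method set, and with exactly
two methods both scores collapse to 0.5 by construction — compare at least
three. Throughput (fps = 1/mean per-frame time) is descriptive metadata
only; it depends on hardware and frame size.

## The synthetic scene

The generator renders an ellipsoidal skin region whose pixels follow

    I_c(x, y, t) = base_c · (1 + flick(t)) + a_c · w(t) + tex_c(x, y) + ε

with base color (180, 120, 100), pulse amplitudes a = (0.45, 1.5, 0.9)
(green strongest, the GREEN method's premise), pulse waveform w(t) a
sinusoid (optionally plus a 0.3× second harmonic) at the configured heart
rate, and sensor noise ε ~ N(0, 0.5²) by default. Dark eye/mouth rectangles
inside the ellipse are static (no pulse, no noise), the background is
static, and per-frame landmarks plus a 60 Hz ground-truth PPG sampled from
the same waveform formula are returned alongside. Frames are 128×128 at
25 fps by default; everything is deterministic given the seed.

Two generator features deserve explanation because the pipeline fails
structurally without them:

* **Static texture** `tex` (uniform ±0.5 intensity, fixed pattern): a
  spatially uniform patch quantizes coherently, so a 0.45-amplitude pulse
  rounds to a *constant* channel and the 1.5-amplitude channel becomes a
  staircase whose harmonics corrupt CHROM/POS. The texture dithers the
  quantizer; patch averages then resolve sub-step amplitudes, exactly as
  real skin texture does for real cameras.
* **Illumination flicker** `flick(t)` (common-mode, relative σ 0.007 along
  the base-color axis; 24 equispaced tones in 2.6–3.8 Hz with seeded random
  phases): the in-band disturbance that LGI/POS/CHROM exist to reject.
  Its total variance exceeds the pulse's, so the dominant data direction is
  the illumination axis and LGI's projection spares the pulse; the tones are
  equispaced to avoid chance clustering into a spectral peak, and the band
  sits above the tested heart-rate range (48–120 bpm) so it never crowds
  the pulse peak. "Noiseless" scenes (sensor σ = 0) keep texture and
  flicker: they model the scene, not the sensor.

What the scene does **not** emulate: facial texture statistics, specular
highlights, non-rigid motion (talking, head rotation), illumination color
changes, camera compression. Passing tests here validates the signal path
and the operators' spectral behavior; it does not predict concealment
margins on real recordings, where errors are dominated by exactly those
phenomena. Motion is limited to rigid linear drift.

Heart rates are restricted to the open band (39, 240) bpm; the configured
amplitude + 4σ noise + texture + flicker must fit inside [0, 255] or the
configuration is rejected.

## Problem sizes used in the shipped checks

Recovery checks run four 30-s clean scenes (48/72/90/120 bpm, 23 windows
each) through all five extractors; the concealment check compares |Δbpm|
before/after TA-S (f = 20) on a 30-s default-noise scene; locality checks
run all eleven operators on a 32×32 scene; noise calibration uses 1.6·10⁵
pixel draws. These sizes give sub-0.1-bpm PSD grids and ±0.25 %-point
binomial error on the 5 % noise fraction.

## Known limitations

* The bilateral filter's window cap deviates from an uncapped
  product-of-Gaussians at extreme σ_space with strong intensity structure.
* AGN-L's local-variance definition (3×3 sample variance, floored) is one
  reasonable reading of "variance depends on local content"; other toolkits
  differ, and AGN-L generally does not degenerate to AGN.
* ICA component selection is deterministic but heuristic; on signals with
  two equally periodic in-band sources it may pick either.
* OS is only comparable within one evaluation run (same method set, same
  normalization scope).
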