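# Methods

## The measurement problem

Each cardiac cycle pushes a bolus of blood through the skin's capillary
bed. Hemoglobin absorbs visible light, so the skin's reflectance dips
slightly with every beat — a modulation on the order of a fraction of one
8-bit intensity quantum per pixel at consumer-webcam settings. Remote
photoplethysmography (rPPG) recovers the heart rate from this modulation
in ordinary video, with no skin contact. The obstacles are (a) the signal
is buried in sensor noise and slow illumination/movement drift, (b) only
skin pixels carry it, and (c) after exercise, breathing and body movement
put a competing low-frequency peak into the spectrum that can exceed the
cardiac peak.

## Pipeline

Seven stages, each an independently testable function:

1. **Spatiotemporal cropping** (`video`). The first and last 3 s are
   discarded (camera gain settling, anticipatory movement); counts are
   rounded up so at least the stated seconds are removed. One fixed
   region of interest per recording — the method assumes a stabilised
   subject; per-frame face tracking is out of scope. Face detection is an
   injected callable (any cascade detector fits the interface); a manual
   box always works.
2. **Skin selection** (`skin`). Automatic mode: k-means (k = 4, squared
   Euclidean distance, ≤ 100 iterations, seeded) on the CIELAB (a, b)
   chromaticity of the ROI pixels; lightness is excluded so shading does
   not split skin into multiple clusters. The winning cluster is the one
   with the most members inside the central half-width/half-height window
   of the ROI ("center of the face"); ties break toward the cluster whose
   centroid is nearest that window's mean chromaticity. Auto mode
   re-clusters every frame with the same seed (robust to slow drift).
   Manual mode: a hue wedge plus saturation band, set once on the first
   frame and reused; defaults (hue 15° ± 25°, saturation 0.15–0.80)
   bracket skin whose mean RGB is near (208, 150, 136), i.e. hue ≈ 12°.
   These wedge defaults are implementation choices, not measured values.
3. **Averaging and detrending** (`traces`). Arithmetic mean of selected
   pixels per frame and channel; averaging m pixels raises SNR by ≈ √m,
   which is why whole-surface averaging works at all. Drift is estimated
   by a zero-phase (forward–backward) sixth-order Butterworth low-pass at
   0.04 Hz (−3 dB of the single-pass design) and subtracted; the output
   fluctuates around zero. **Padding choice:** this filter's impulse
   response spans tens of seconds, so reflection padding must span a
   comparable stretch (we use ⌈1.5·fs/fc⌉ samples, capped at n−1).
   Even (zero-slope) reflection is used: with odd reflection, an
   oscillatory trace reflected at arbitrary phase injects spurious
   low-frequency content and the drift estimate inherits percent-level
   edge error; with even reflection the measured transfer function
   matches the analytic |H(f)|² = (1+(f/fc)^{2·order})^{−1} zero-phase
   response to better than 2% from passband through cutoff. Deep-stopband
   behaviour follows the bilinear-prewarped digital response, as for any
   digital Butterworth.
4. **ICA** (`ica`). Symmetric (stabilised, parallel) FastICA, log-cosh
   contrast, 3 components, ≤ 2000 iterations, seeded and deterministic.
   The cardiac source enters all channels with different weights while
   noise is largely channel-independent, so one component concentrates
   the pulse. Rank-deficient input yields fewer components with a log
   note; non-convergence is flagged, not fatal. Components are
   unit-variance; they are defined only up to sign and order, which is
   irrelevant downstream because power spectra are sign-invariant.
5. **Power spectra** (`spectrum`). One-sided squared-magnitude FFT, axis
   in BPM (Hz × 60); bin width 60·fs/n BPM bounds achievable precision
   (2.5 BPM for 24 s of 30 fps video).
6. **Spectral smoothing.** Heart rate drifts during a recording, smearing
   the cardiac peak into clusters of small peaks; a zero-phase
   third-order Butterworth low-pass applied *along the frequency axis*
   (normalized cutoff 0.2 × the bin sequence's Nyquist) merges them.
   Zero-phase symmetry cannot shift an isolated peak by more than one
   bin (tested); a 2-bin doublet merges into one maximum (tested).
   Negative overshoots are clipped to zero.
7. **Peak selection with respiration rejection.** Candidate peaks are
   strict local maxima (plateaus reported once, at center) of the
   smoothed spectrum inside the peak-search band, sorted by height.
   Default selection: the highest peak across components. Rejection
   rule: if the highest peak lies below 90 BPM while some peak above
   90 BPM reaches ≥ 70% of its height, the tallest such above-cutoff
   peak is selected instead — post-exercise breathing/movement often
   dominates the spectrum while the true cardiac peak sits above 90 BPM.

### Bands

Two distinct bands are deliberate:

* **Peak-search band, default 24–200 BPM.** The rejection rule exists to
  discard a *respiration* peak, and post-exercise breathing sits around
  24–40 BPM; the rule can only see that peak if the search floor lies
  below it. `find_peaks` itself defaults to the physiological band.
* **HR validity band, default 40–200 BPM.** A final estimate must be a
  plausible heart rate. If the leading component's selection falls
  outside this band (e.g. ICA isolated respiration into its own
  component, whose only peak is ~30 BPM), the next-strongest component
  is tried. The no-rejection ablation (`use_resp=False`) skips both the
  rule and this fallback: it is exactly the "highest power peak across
  components" baseline that the rejection rule was introduced to
  improve, and on respiration-dominant recordings it fails by design.

Whether the winning component is chosen on raw or smoothed power is not
uniquely determined by the method's description; smoothed power is used,
consistent with peak selection.

## Synthetic data

`SynthSpec` generates traces and 8-bit RGB videos with the structure the
method assumes: a skin rectangle at mean color (208, 150, 136) on a
contrasting background, cardiac sinusoid of amplitude `hr_amp` with
per-channel weights (0.5, 1.0, 0.3) — green strongest, a modelling choice,
configurable — optional respiration sinusoid and slow illumination drift,
and per-pixel Gaussian sensor noise. Defaults: 30 fps, 30 s, 60×60 px
frame with a 40×40 skin box, hr 75 BPM, hr_amp 2, noise_sd 1, respiration
and drift off (opt-in confounds).

Respiration enters **through the cardiac channel weights by default**:
respiration modulates venous return and hence blood volume, so its
optical signature shares the hemoglobin color direction, and after
spatial ICA both the respiration and cardiac peaks then appear in a
*single* component spectrum — the exact confound the rejection rule
addresses. With achromatic weights (1, 1, 1), spatial ICA separates
respiration into its own component instead, and the rule is never
exercised; that variant remains available via `resp_weights`.

A cardiac sinusoid (no pulse-shaped harmonics) suffices because the
method uses only spectral peak location. Per-pixel noise doubles as
dither: sub-quantum modulation (hr_amp < 1) survives 8-bit quantization
only if noise_sd ≥ ~0.5, hence the generator's warning.

What the generator does *not* emulate: subject motion, face geometry,
codec compression, specular highlights, ambient light flicker, heart-rate
variability within a recording. Passing tests therefore demonstrate the
pipeline's correctness and its noise/confound behaviour under the model's
assumptions, not field performance on arbitrary recordings.

## Accuracy report

`report` implements the standardized agreement summary: Spearman rank
correlation (average ranks on ties; minimum of three data points),
mean ± sample SD of the absolute difference |rPPG − reference| per
condition cell, Bland–Altman bias with bias ± 1.96·SD limits of
agreement, correlation as a function of analyzed record length, and
distribution distinctiveness as ROC AUC (midrank tie convention) with a
separability percentage 100·(2·AUC − 1), clipped below at 0 — the mapping
that reproduces published (AUC, %) pairs within ±1 point. Repeated-
measures ANOVA / post-hoc t tests are intentionally left to general
statistics tools; the report emits tidy tables they can consume.

## Problem sizes and numerics

Validation runs use 20 recordings of 30 s at 30 fps and 60×60 px per
scenario — enough to make one wrong video a 5% step in the hit rate while
keeping a full run in minutes on one core. Recovery tolerance is one
spectral bin (2.5 BPM at 24 s usable). k-means uses a single seeded
initialisation; FastICA tolerance 1e-4; effective rank is judged at 1e-8
relative singular value. Degenerate inputs: chromatically uniform ROIs
fall back to the full box with a warning; rank-deficient traces yield
fewer ICA components; an empty peak list raises a structured estimation
error that batch processing records as a failure row.

## Known limitations

* One fixed ROI per recording; no motion compensation or tracking.
* The AVI reader/writer handles only uncompressed 24-bit RGB (the
  container the reference camera produced); compressed video must be
  transcoded first.
* Heart-rate variability is represented only through the smoothing
  stage's merging behaviour, not simulated explicitly.
* The exact ICA nonlinearity of the original analysis software is
  unknown; log-cosh is the documented default and is configurable in
  code.
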