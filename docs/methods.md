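# Methods

## Scope and model

The package quantifies anaphase B (spindle elongation) and the processes
coupled to it from 2-D fluorescence time-lapse movies. Positions are
continuous μm coordinates with the center of pixel (0, 0) at the metadata
origin, x rightward, y downward; frame `k` is acquired at
`k × frame_interval` seconds. z is ignored throughout: tracking, profiles
and kymographs are 2-D, matching the single-plane or max-projection
acquisition the pipeline is designed for. Only the astral microtubule
length measurement takes 3-D polylines.

### Spindle kinematics

Two poles sit on the x axis at ±L(t)/2. L(t) is constant at the metaphase
spindle length before anaphase onset and then grows linearly at `v_B`
(μm/min). Each sister kinetochore approaches its pole at `v_A`
(anaphase A), clamped at a minimal pole distance, so the sister-centroid
distance grows at `v_B + 2 v_A` while unclamped. Localization error is
emulated by adding isotropic Gaussian jitter (default 0.05 μm) to every
coordinate after the trajectories are built. Defaults encode a control
condition: `v_B = 2.36` μm/min, `v_A = 0.5` μm/min, 12 μm spindle, 1 μm
sister distance, 15 s frames, onset at 60 s; perturbed conditions are
modeled by lowering `v_B` (≈ 0.35–0.55 μm/min for a double motor
perturbation).

### Rendering

Objects are rendered as PSF-blurred shapes integrated exactly over the
pixel grid (error function integrals): points become 2-D Gaussians of
sd `psf_sigma` (default 0.11 μm on 83 nm pixels); the photoactivated band
uses PSF-smoothed rectangles. Noise is Poisson shot noise on signal plus
background followed by additive Gaussian read noise; the paper-facing SNR
is defined as spot peak over `sqrt(background + read_sd²)`. Background
models diffuse fluorescence, so the per-frame bleach factor
`exp(-bleach_rate t)` applies to it as well. With noise and bleach off,
per-object integrated intensity is conserved over time to < 0.1%.

### Photoactivated band

The band is a line of `n_points` activation spots (default 10, spaced
0.5 μm) perpendicular to the spindle axis at the midzone center. Each
spot splits into two rigid half-bands of axial width `band_thickness`
(0.5 μm) translating apart at ±`v_slide`/2, so the true band extent is
`band_thickness + v_slide·t/60`. Turnover is a single multiplicative
survival factor interpolated exponentially, `survival_30s^(t/30)`; only
the 30 s ratio is ever measured, so no faster/slower two-population
unmixing is attempted. PA movies default to 0.8 s frames and 200 frames.

Half-bands are rectangles rather than Gaussians deliberately: the
measured band edge of a rectangle moves at `v_slide/2` from the first
frame, whereas two separating Gaussians only change their threshold
width at second order until they are optically resolved — with Gaussian
halves the assay could not report slow sliding at all.

### EB3 comets

Comets nucleate at Poisson times: astral comets near a pole (0.3–2.5 μm
out) moving radially away from the other pole, midzone comets uniformly
inside the midzone rectangle moving axially in either direction, both at
`v_comet` (default 20 μm/min) with exponential lifetimes (default 8 s).
A comet dies at its lifetime or at the cell boundary; frames with the tip
within `contact_distance` (default 0.5 μm) of the boundary are cortex
contacts. The cell is an ellipse, the astral regions are bounded by the
through-pole perpendicular lines, and the midzone rectangle spans the gap
between the two chromosome blocks (from an H2B mask: Otsu threshold, two
largest components, facing edges).

## Estimators and numerical choices

* **Spot detection**: candidate maxima above an intensity offset (default
  median + 5 robust sd) are refined by least-squares 2-D Gaussian fits in
  a `(4σ₀+1)²` window; fits escaping to the σ bounds are rejected as
  noise spikes; duplicates within σ₀ are merged keeping the higher
  amplitude. The fit is plain least squares rather than an EMCCD
  likelihood (camera gain parameters are not modeled); the test suite
  bounds the gap against a grid-search ML oracle on identical frames.
* **Linking** is greedy globally-nearest per frame transition with a hard
  displacement gate and gap closing; ties break by smaller amplitude
  change, then object id. On random-walk benchmarks it agrees with the
  exhaustive Hungarian matching in ≥ 95% of transitions at a fraction of
  the bookkeeping.
* **Onset detection**: last frame before the first run of ≥ 2 increasing
  steps whose total rise exceeds `noise_floor` (default 2× the pre-onset
  step jitter). Two robustness rules are layered on: the rise must be
  sustained (the next four frames must stay more than `noise_floor`
  above the starting level), and weak leading steps — below half the
  noise floor or half the run's mean step — are trimmed so a noise uptick
  chaining into the real rise cannot pull the onset early.
* **Bleach correction** for tracking uses histogram matching to a
  reference frame. The stability ratio does *not*: matching whole-frame
  histograms would equalize the activated band too and cancel the very
  turnover being measured. Instead a bleach factor is estimated from the
  unactivated cytoplasm (border-ring mean relative to the activation
  frame) and divided out.
* **Background** is the pooled pixel mean of the frame's corner blocks,
  excluding corners whose median is many noise-sd brighter than the
  dimmest (structures); a plain minimum or low quantile would sit
  systematically below the true level under shot noise.
* **Stability ratio**: profiles averaged across the line thickness;
  both time points integrated by trapezoid over one fixed support (the
  union of both frames' above-threshold band supports, padded 0.4 μm for
  PSF tails); the unclipped profile is integrated so noise cancels
  instead of rectifying; a residual offset measured in the off-band part
  of the profile is subtracted. Each time point averages
  `frame_avg = 5` consecutive frames — with exponential decay and
  identically shaped windows the averaged ratio still measures exactly
  the 30 s decay, at √5 lower shot noise. The profile thickness should
  roughly match the band's lateral extent (56 px for the default
  10-point band); an oversized thickness only dilutes SNR.
* **Band width / sliding**: `band_width()` is the deterministic
  edge-threshold width (outermost crossings of `edge_fraction` × peak,
  default 0.2, with sub-pixel interpolation; contiguous segments must
  reach half the peak to count as band halves). Threshold crossings are
  diffraction-limited, so the sliding pipeline (`pa_assay`,
  `fit_band_widths`) instead fits all frames jointly with the two-half
  model: global thickness, PSF, center and a linear separation
  `sep(t) = b·t` (the halves coincide at activation by construction);
  per-frame amplitudes are profiled out in closed form. Because the
  separation magnitude cannot go below zero, a likelihood-ratio gate
  (χ², 1 dof, 95th percentile) reports zero sliding unless the sliding
  model fits significantly better — this keeps the zero-sliding control
  unbiased. Multiple optimizer starts handle the stationary point of the
  (even) cost at b = 0.
* **Comet detection**: scale-normalized LoG at σ = diameter/(2√2), with
  quality defined as response over twice the robust per-pixel noise sd.
  This calibration makes the conventional threshold value 0.8 reject
  blank-noise frames while keeping comets of peak SNR ≥ 8; the threshold
  can also be auto-raised until ≤ 5% of detections fall outside the cell
  boundary, the standard detector acceptance rule. Sub-pixel positions by
  quadratic interpolation of the response.
* **Kymograph tracing**: probabilistic Hough lines on the thresholded
  kymograph seed each trace, which is then refined against the intensity
  ridge (per-frame centroids in a window around the line, skipping frames
  without clear signal). Traces with ridge-fit RMS above 1 px (stitched
  across crossing comets), duplicates of an already-kept longer trace,
  or spanning fewer than 8 frames are dropped — the operational
  equivalent of tracing only *discernible* comets. Comet motion is
  projected onto the kymograph line, so lines should follow the motion
  direction (the spindle axis for midzone comets).
* **Statistics**: classical pooled-variance unpaired and paired t-tests,
  two-sided, with the usual star scheme; Spearman rs as the Pearson
  correlation of midranks, with an OLS overlay line on the raw values for
  plotting. No multiple-testing correction is applied — comparisons are
  reported individually, as is conventional for these per-condition
  phenotype panels; users comparing many conditions at once should
  correct externally.

## Validation by parameter recovery

`spindleq.validation` scores every stage against the generator (all
randomness spawned from one master seed): elongation velocity on 50
jittered track sets per velocity against the analytic OLS slope-error
formula; onset recovery on 100 jittered series; stability-ratio recovery
at survivals 0.5/0.7/0.9 (20 SNR-10 movies each, with bleaching);
sliding recovery at 0.5/1/2 μm/min plus a zero control (20 movies each);
comet precision/recall on 3 movies at SNR 8 plus the region-assignment
oracle, the Poisson nucleation check and the kymograph velocity; the
statistics layer against brute-force midranks, numerical t-CDF
integration and a KS uniformity test of 2000 null p-values; and a 20-cell
two-condition end-to-end cohort run twice to confirm bit-identical
determinism. These problem sizes keep the whole benchmark under two
minutes on one CPU while leaving each criterion statistically meaningful;
recovery criteria are evaluated on the mean across a suite's movies,
since a single SNR-10 frame pair carries irreducible shot-noise scatter.

## What the synthetic data does and does not show

The generator reproduces the *geometry and statistics* the estimators
rely on: linear kinematics with a sharp onset, PSF-blurred spots and
bands with Poisson-Gaussian noise, exponential turnover and bleaching,
Poisson comet appearance. It does not emulate uneven illumination,
spatially varying background, chromosome-mass occlusion of kinetochores,
comet shape anisotropy, spindle rotation during the movie, z drift, or
acquisition-specific noise statistics (no instrument calibration exists
for it — synthetic SNR is a free parameter). Passing the recovery suites
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every artifact of real microscopy; the
config-exposed thresholds (intensity offset, noise floor, edge fraction,
quality threshold) are the knobs a user would retune on real data.

## Known limitations

* Sister pairing is mutual-nearest-neighbor at onset and fixed
  thereafter; crowded kinetochore fields can mis-pair.
* The sliding fit assumes two symmetric half-bands with a linear
  separation over the 30 s window; strongly asymmetric sliding or
  mid-window arrest would bias it.
* Kymograph tracing reports per-trace velocities only; it does not
  reconstruct full 2-D+time comet trajectories.
* The whole-spindle intensity region for EB3-style comparisons is the
  supplied polygon; no attempt is made to standardize it anatomically.
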