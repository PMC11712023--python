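# Methods

This note documents the models, conventions, and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the limitations a user should keep in mind when moving from
simulated to real microscopy data.

## Coordinate and sampling conventions

All image operations use x-right / y-down coordinates with the origin at
the **center** of the top-left pixel; physical positions are
`µm = px × pixel_size`. A pixel belongs to an ROI when its center lies
inside or on the shape boundary — a deterministic, enumeration-checkable
stand-in for the GUI ROI rasterization the original workflow relied on.
Frame times are `frame index × frame_interval` seconds from the first
frame.

## Smoothing

`moving_average(stack, window)` replaces each pixel by its
window × window neighborhood mean, per frame (never across time).
Boundaries are handled by edge reflection (`abcd → ba|abcd|dc`). Even
windows have no central pixel; the footprint is floor-centered with its
top-left corner at offset (−1, −1), so the 4×4 window covers offsets
−1..+2 on both axes. This anchoring is applied identically everywhere and
is pinned by a brute-force oracle test. The tip-tracking path uses a 3×3
window and the ratiometric path a 4×4 window, matching the conventions of
the quantifications they reproduce.

## Kymograph and the tip-distance statistic

The midline path is supplied tip-first (column 0 = tube tip). At each
path point the local tangent comes from central differences;
`line_width` (default 10) samples are taken along the perpendicular at
1-px spacing, bilinearly interpolated, and averaged. Per-frame paths of
unequal length are truncated to the shortest so no column ever refers to
unimaged tube. For growing tubes the per-frame path is re-anchored at the
instantaneous tip position; the tube simulator emits exactly these paths,
and real use expects user-supplied ones.

`binned_tip_distances` slides a `bin_height_px` (10) window down the time
axis in `step_px` (5) steps — bins start while `start + bin_height ≤
n_rows`, giving `floor((rows − bin)/step) + 1` bins (29 for 150 rows).
Each bin's rows are averaged column-wise (mean rather than sum; argmax is
unaffected but the choice is fixed for reproducibility) and the bin's
distance is the argmax column × pixel size, ties broken toward the tip
(deterministic and conservative). The tube's statistic is the mean over
bins. Group comparison reports mean, SD, SE and box statistics per group
plus pairwise two-tailed Student's *t*-tests; dispersion is reported as
both SD and SE since figure conventions vary.

## Ratiometric Ca²⁺ analysis

`ratio_stack` computes `scale × YFP/CFP` per pixel (scale 4000 by
convention). Pixels whose CFP falls below a floor — default 1% of the CFP
dynamic range — are masked (NaN) and excluded from ROI means, preventing
background pixels from blowing up the ratio. `display_rescale_to_first`
is a display-only affine map (first-frame min → 0, max → 1) and refuses
already-rescaled input; all analysis consumes raw ratios.

Spike timing operates on a first-point-normalized ROI trace. The **rapid
drop** is operationalized as the first sample below
`(1 − drop_fraction)` × the running maximum over the trailing
`drop_window_s` (defaults 0.15 and 120 s) — the original criterion was
applied by eye, so these are exposed parameters, not an inference of the
authors' threshold. The **post-drop minimum** is the first trough after
the drop (not the window's global minimum, which could land after an
early spike). The **spike** is the first subsequent local maximum within
`search_window_s` (default 900 s — the spike is an early-hydration
event, and how tightly the original search was bounded is not stated).
To reject single-sample noise blips, peak finding runs on a lightly
smoothed copy (3-sample boxcar) with a prominence floor (0.1 on the
normalized trace), then refines to the raw trace's local maximum; plateau
peaks resolve to their first sample. Hydration start is an input per
grain (the simulator emits it); traces are assumed to begin there.
`align_to_spike` shifts time axes so every spike lands at a common anchor
(5 min by convention).

## Peak detection and lag estimation

`detect_local_peaks` wraps prominence-based peak finding (default
prominence 0.05 on first-frame-normalized traces, minimum separation
1 min; plateaus resolve to their first sample). `peak_lag` matches each
reference peak, in time order, to the earliest unused response peak at or
after it within `window_min` (default 5 min) — forward greedy matching,
chosen because the response reporter is reported to peak *after* the
reference; unmatched reference peaks are counted rather than silently
dropped, since whether such peaks were excluded or simply absent in the
original traces is unknowable. Lags are reported with both SD and SE.

## Co-migration screening

Profiles are row-normalized to sum to 1 (proteins with zero total
abundance are excluded with a report; a zero-total bait is fatal).
Pearson r is computed between each protein's fraction vector and the
bait's; passing is **strictly** r > cutoff (0.8). Zero-variance profiles
have undefined r and never pass. With only four fractions r is coarse,
and the module refuses tables with fewer than three fractions. Both raw
and normalized tables can be screened — Pearson r is affine-invariant, so
for positive profiles normalization does not change pass/fail (property-
tested); normalized is the default. Co-IP comparison is presence/absence
by protein id (no abundance threshold is implied by a detection list).

## Statistics

Student's pooled-variance two-tailed *t*-test is the default (Welch
behind a flag); the degenerate both-groups-zero-variance case returns
p = 1 for equal means and p = 0 otherwise. The segregation test is a 1-df
chi-squared against a 1:1 expectation. Multi-group comparisons use
one-way ANOVA + Tukey HSD (cross-checked against an independent
implementation). Box statistics use linear-interpolation quartiles with
whiskers at the most extreme points within 1.5 × IQR of the quartiles and
the rest listed as outliers.

## Synthetic-data generators

Each generator's defaults are the acquisition conditions of the
quantification it emulates, and each emits a `SynthTruth` record
sufficient to score the downstream statistic.

- **Tube** (`simulate_tube_movie`): a 2-D capsule of fixed 5-µm width
  whose tip advances with an oscillatory velocity (default growth
  0.02 µm/s, oscillation period 50 s, amplitude 0.5 µm — mid-range for
  angiosperm pollen tubes); fluorescence is background plus a Gaussian
  band (σ 1 µm) centered `band_distance_um` behind the instantaneous tip;
  150 frames at 3 s, 0.2 µm/px; default noise 10% of band amplitude.
- **Dual-reporter grain** (`simulate_grain_dual_channel`): an elliptical
  grain (semi-axes 10 × 8 µm) with a 2.5-µm-radius polarized site;
  channel 2's site oscillation trails channel 1's by `lag_min`
  (default 2.74) on a 6-min period at 1-min sampling; each grain draws a
  random oscillation phase, both because real grains polarize
  asynchronously and so frame-quantization error dithers out across a
  cohort; noise 3% of background.
- **FRET movie** (`simulate_fret_movie`): CFP constant inside a circular
  grain; YFP = CFP × r(t) where r(t) is baseline → linear fall
  (depth 0.4 over 60 s from 1.5 min) → brief Gaussian spike (FWHM 20 s,
  default center 4.87 min) → gradual rise (0.02/min); 10-s frames over
  30 min. `noise_sd` (default 0.05) is the target SD of the ROI-averaged
  normalized ratio trace and is applied as per-frame multiplicative
  jitter on the acceptor plus per-pixel truncated Gaussian noise —
  per-pixel noise alone would average away over the ROI and leave traces
  unrealistically clean.
- **Fraction table** (`simulate_fraction_table`): the bait profile is
  drawn once from a Dirichlet; planted co-migrators (the set includes the
  bait itself) are the bait plus truncated Gaussian noise, renormalized;
  background proteins are flat-Dirichlet draws **rejection-sampled to
  r ≤ cutoff against the bait** — an unconstrained 4-point Dirichlet
  profile chance-correlates above 0.8 with a typical bait in roughly one
  draw in eight, which would make planted labels meaningless as ground
  truth. Defaults are full screen scale (3046 proteins,
  340 co-migrating).
- **Callose z-stacks** (`simulate_callose_zstack`): three slices at 3-µm
  spacing per grain; positive grains (Bernoulli, default prevalence
  0.726) receive Gaussian spots (σ 1 µm, truncated at 3σ so the
  noiseless background stays exactly constant) placed with a minimum
  separation so planted spots remain distinct after projection.

Noise everywhere is additive Gaussian truncated at zero. The generators
do **not** model optical point-spread functions, photobleaching, focus
drift, 3-D geometry, shot-noise statistics, autofluorescent pollen exine,
or spectral bleedthrough — so passing recovery tests demonstrates that
the estimators are correct and robust to moderate additive noise, not
that they are robust to every artifact of real confocal data. Real use
still requires user-drawn ROIs and midline paths, as in the original GUI
workflow.

## Spot counting

Projected images are binarized at either a fixed threshold or
median + k·MAD (default k = 5) of the whole image; 8-connected components
of at least `min_area_px` (default 4) are spots. The original scoring was
visual, so these defaults are placeholders for a size/intensity criterion
that was never stated, and both are config-exposed. Raising the threshold
never increases the count on spot-like (unimodal-blob) images; on
arbitrary images a component can split above a saddle, so monotonicity is
only guaranteed in the detector's intended regime.

## Problem sizes and determinism

Recovery properties are checked at full-scale conditions: 100 seeded
replicates of 150-frame tube movies for the noisy tip-distance band, ten
grains for the pooled lag, 20-grain cohorts for spike-time comparisons,
a 3046-protein table for the screen, and 500 grains for prevalence.
Every generator draws from a single `numpy` Generator per call, so a
fixed seed reproduces outputs bit-identically, and pipeline runs with the
same config and seed write byte-identical CSVs.

## Known limitations

- Tip anchoring for real data depends entirely on the supplied per-frame
  midline; errors in tip placement translate 1:1 into distance bias.
- The spike detector's drop/prominence parameters are an
  operationalization; traces whose hydration drop is slower than
  `drop_window_s` will not trigger detection.
- Peak matching is greedy and directional; for lags approaching the
  oscillation period, matching becomes ambiguous and the window must be
  chosen below the period.
- With four fractions, Pearson r takes coarse values; the strict 0.8
  cutoff can flip on small abundance perturbations near the boundary.
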