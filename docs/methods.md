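# Methods

This note records the models behind each pipeline, the parameters that
matter with their defaults and units, the design choices made where the
design was genuinely open, and what the synthetic-data validation does and
does not establish about real movies.

## Coordinate and calibration conventions

One convention holds package-wide: pixel indices are 0-based, `x` is the
column and `y` the row, origin at the top-left (`y` increases downward);
angles come from `atan2(vy, vx)`. All CSV outputs are in pixels; physical
conversion uses the calibration carried by `MovieStack` (`pixel_size`,
µm/pixel; `frame_interval`, s) and happens only at metric time. On read,
explicit calibration arguments beat TIFF metadata, and a movie with
neither raises rather than assuming a default.

## Synthetic bead movies

The simulator emulates the two acquisitions the pipelines consume.

**Transport assay.** The field of view is divided into a `patch_grid`
(default 8×8) of flow patches. Exactly `round(active_fraction · n_patches)`
patches are active; each active patch gets a direction drawn from a
two-component mixture — with probability `coherence` the movie-wide shared
direction, otherwise an independent uniform draw — and a speed
`mean_speed · (1 + speed_cv·ε)` truncated at zero. Beads are advected each
frame by the velocity of the patch they currently occupy (plus any
whole-frame drift), rendered as Gaussian spots (`bead_sigma`, default
1.5 px; constant amplitude 80 above a background of 10) with additive
Gaussian sensor noise (`noise_sd`, default 2), quantized to 16-bit. Beads
leaving the frame are removed. Defaults mirror the assay acquisition:
300 frames at 0.1 s interval. Pixel size defaults to 1 µm/px — a free
choice of the simulation, since neither assay's optics pin it down.

**Embryo assays.** For bead tracking, the same machinery is used at an
embryo-like calibration of 0.5 µm/px and 0.5 s/frame (dissecting-scope
imaging is coarser and slower than the culture assay), so the slowest
speeds probed (0.5 µm/s) still move half a pixel per frame. For drift, a
dark textured ellipse (analytic sinusoidal texture, so it translates
exactly) moves across a bright background at `drift_velocity`; the exact
centre series is the ground truth.

Deliberate simplifications, and their consequences for what the tests
show: flow is piecewise-constant per patch with no interpolation, so
"active area" and "per-patch direction" are exact truths but patch borders
host velocity discontinuities no real epithelium has; beads do not diffuse
by default (`diffusion_sd = 0`), keeping kinematic oracles exact; bead
photometry is constant (no bleaching) because all reported metrics are
kinematic. A specific artifact of the piecewise flow: where neighboring
patches point toward each other, beads oscillate at the border instead of
passing through, so at sparse seeding the swept area per bead is shorter
in incoherent flow than in coherent flow. Validation experiments that
compare moving *area* across coherence levels therefore use seeding dense
enough to saturate coverage of the driven area, where the moving mask
measures the area itself rather than trajectory lengths.

Passing tests on these movies demonstrates correct recovery of known
kinematics through the full imaging chain (rendering, noise,
quantization). They do not exercise mucus rheology, uneven illumination,
bead aggregation, or focus drift, all of which real movies contain.

## PIV pipeline

**Displacement estimator.** For each interrogation window (default
32 px, 50 % overlap) and frame pair `(t, t + pair_spacing)` the window is
matched against a search region of the later frame extended by
`max_disp` (default `window/3`) on each side, with zero-normalized
cross-correlation: the numerator is the linear (zero-padded FFT)
correlation of the zero-mean template, the denominator the local energy
of the search region under the template support at each lag. Local
normalization matters: correlating same-size windows circularly biases
the subpixel peak by up to half a pixel through edge truncation, which a
noise-free uniform-translation oracle exposes immediately; the
template-with-margin ZNCC passes that oracle with ≈ 0.05 px worst-case
error at dense seeding. The subpixel peak is refined per axis by a
3-point Gaussian fit on the correlation values (parabolic fallback when a
neighbor is non-positive; no refinement when the peak sits on the search
border). Peak quality is the first-to-second peak ratio with a 3×3
exclusion zone; windows whose median ratio falls below 1.1, or with zero
variance, are invalid and excluded from every numerator *and*
denominator.

**Temporal aggregation.** The window velocity is the vector mean of
per-pair displacements, so incoherent jitter cancels and the window speed
measures directed transport — the quantity the assay is about. The
per-pair scatter around that mean is retained per window.

**Noise floor (active definition).** The exact per-window activity rule
used on the original assays is not public, so the package defines its
own, self-calibrated from the movie being analyzed. Two terms are
combined, the larger winning:

* *jitter null*: with no directed transport, per-pair displacements are
  zero-mean with per-component SD σ, so the vector-mean magnitude is
  Rayleigh with scale σ/√n_pairs; the floor takes the 95th Rayleigh
  percentile (2.448 σ/√n) of a conservatively pooled σ (the 90th
  percentile of per-window scatter) times a safety factor of 2;
* *resolution floor*: 0.25 px per pair. A static texture produces a
  small pattern-determined subpixel bias that repeats identically every
  pair — invisible to the jitter term — and displacement below a quarter
  pixel per pair cannot be certified as motion by window correlation.

A temporally-shuffled-movie floor (shuffle frames, re-run PIV, take a high
percentile) was evaluated and rejected: shuffled frame pairs of an
advected scene carry real multi-frame displacements of magnitude
|tᵢ−tⱼ|·v, so the "null" lands far above the true signal and the activity
metric degenerates. With the two-term floor, fully static noisy movies
classify as exactly 0 % active while windows driven at assay-scale speeds
clear the floor by an order of magnitude.

**Field of view.** Circular mask, either at a fixed radius fraction of
half the short image side (values above 1 reach the corners, giving a
full-frame FOV for edge-effect-free validation) or fitted automatically
to the bright culture area of the temporal-mean image (Otsu threshold,
largest component, enclosing circle).

**Threshold metric.** `percent_above_threshold` counts in-FOV valid
windows whose speed exceeds an externally supplied reference and which are
also active, making the nesting `percent_above_threshold ≤ percent_active`
structural. The reference implements a "mean control speed": the mean of
speeds over *active* in-FOV windows pooled across the designated control
movies of a batch. Pooling over active windows only is a documented
choice — including static windows would drag the reference toward zero
and make the metric degenerate as controls vary in active area.

## Coordination pipeline

**Moving mask.** The per-pixel temporal statistic is the intensity SD
over time (IQR/1.349 available as a robust alternative). Its static
(noise-only) level is estimated from the movie itself: for a static pixel
the SD over T frames concentrates around the noise SD with relative
sampling spread `c = 1/√(2(T−1))`, so the 10th percentile of the SD map —
a statistic of the quietest pixels, valid as long as a few percent of the
field is not genuinely moving — rescaled by `1/(1 − z₁₀·c)` estimates the
static level, and a pixel is moving when its SD exceeds that level by
`k_sigma` (default 3) sampling spreads. The mask is cleaned by a binary
opening and removal of components under 20 px. Simpler global
median+MAD thresholds fail in exactly the regime the assay produces
(densely swept fields leave no majority background); the quantile-based
null handles both extremes, giving exactly 0 % on static-but-noisy movies
and ≈ 80–95 % on densely swept ones.

**Block directions.** The field is tiled into blocks (default 32 px). A
block enters the direction field when at least half of its in-FOV pixels
are moving (in-FOV-relative, so circular-FOV boundary blocks are not
disqualified by pixels that can never move); its direction is the angle
of the vector-mean displacement from the same ZNCC estimator (window =
block, no overlap), and blocks with invalid correlation are dropped.

**Coordinated mask.** For each moving block, alignment is the mean
resultant length R of unit direction vectors over a disk neighborhood of
radius 2 blocks (inclusive of self); blocks with fewer than 3 moving
neighbors are unscored and counted uncoordinated; coordinated ⇔
R ≥ R_min (default 0.8). R is the standard circular-coherence statistic:
1 in the fully aligned limit and E[R] ≈ 0.886/√n under the uniform
(Rayleigh) null, so the two ends of the coherence axis are cleanly
separated. Area accounting is at pixel level — coordinated area = moving
pixels inside coordinated blocks — which makes
`coordinated_fraction ≤ moving_fraction` and
`coordinated_of_moving ∈ [0, 100]` identities rather than approximations.

## Tracking and drift

**Detection.** Spots are local maxima of the scale-normalized negated
Laplacian-of-Gaussian response at `spot_sigma`, thresholded at
`median + snr_min · σ_MAD` of the response plane, refined per axis by a
quadratic fit. Detections within 2.5 σ of each other are flagged as
possible merges.

**Linking.** Greedy mutual-nearest-neighbor: candidate pairs within
`max_displacement` are accepted in order of increasing distance, each
endpoint once. Matching proceeds in rounds of increasing staleness —
direct frame-to-frame links strictly outrank gap-closing links (up to
`max_gap = 2` skipped frames, cutoff scaled by the gap), so a stale track
can never steal a detection from a track seen in the previous frame;
without that ordering, uniform co-moving fields produce tied candidates
and identity theft. Tracks shorter than `min_track_length` are discarded.
A full linear-assignment linker is a possible extension; at assay bead
densities the greedy linker reproduces ground-truth tracks exactly.

**Speeds.** Per-track speed is total path length over elapsed time
(matching the track-speed semantics of common spot trackers); a
net-displacement speed is emitted alongside. The per-specimen speed is the
unweighted mean over tracks.

**Drift.** Each frame is segmented by an Otsu threshold (dark object by
default; polarity configurable), the largest component above 50 px is the
specimen, and its centroid series gives `drift_speed` (net displacement
over elapsed time) and `drift_path_ratio` (net over total path; defined
as 0 when the total path is zero). Segmenting the temporal-median-
subtracted frame was considered and rejected: for a stationary or slowly
drifting specimen the temporal median contains the specimen itself and
subtraction erases it, whereas per-frame thresholding handles both the
stationary and the drifting case.

## Group statistics

Pipelines emit tidy metric rows; `summarize_groups` reports mean, sample
SD and n per (batch, group, metric). The built-in significance check is a
seeded two-sided permutation test on the difference of group means with
the add-one estimator (p ≥ 1/(n_perm+1)); its type-I error is verified at
nominal level over null simulations. Factorial ANOVA and mixed models are
deliberately out of scope — the exported tables are shaped for direct
import into any statistics package.

## Validation problem sizes

The validation experiments (shared by the test-suite and
`scripts/acceptance.py`) run on 256 px fields (384 px for the coordination
sweep, giving 144 independent direction blocks), 16–24 frames, and
seeding from ~1 200 beads (classification experiments) to ~4 000 beads
(PIV subpixel oracle and coverage-saturated moving-area comparisons) —
sizes chosen so a full run finishes in a few minutes on one CPU while
leaving every tolerance comfortably met. The PIV oracle uses
`bead_sigma = 0.8` and dense seeding because window correlation is a
statistical estimator: its subpixel accuracy is set by the number of
sharp, countable texture elements per window, and ~18 beads/window at
σ ≈ 0.8 px is the regime the method is designed for.

## Known limitations

* The simulator's flow field is piecewise-constant; none of the smooth
  vortical structure of real cilia-driven flow is modeled, and patch
  borders trap beads under incoherent flow (see above).
* The noise floor and moving-mask null are self-calibrated per movie and
  assume at least a few percent of genuinely quiet area (moving mask) or
  sane per-pair jitter statistics (PIV floor); pathological movies (e.g.
  saturating illumination flicker) would need explicit thresholds, which
  every entry point accepts.
* `percent_above_threshold` depends on an externally chosen reference
  speed; cross-batch comparisons are only meaningful with a consistent
  control-derived threshold per batch.
* The linker is greedy; at densities where beads routinely pass within
  one step of each other, a global assignment linker would be safer.
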