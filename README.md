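# ciliaflow

Quantification of cilia-driven bead transport from time-lapse fluorescence
movies, for labs measuring mucociliary clearance on airway epithelial (ALI)
cultures or on *Xenopus* embryo surfaces.

Motile cilia on multiciliated cells drive a directional surface flow. The
standard functional readout is a **bead assay**: fluorescent tracer beads are
placed on the epithelium in a viscous medium and filmed (typically 30 s at
10 frames/s); how much of the surface moves the beads, how fast, and how
*coordinated* neighboring regions are all report on ciliary function.
`ciliaflow` implements three complementary quantification pipelines plus a
synthetic movie generator that provides exact ground truth for validating
every metric.

## The pipelines

**PIV pipeline** (`ciliaflow.piv_cambridge`). For each interrogation window
*w* and frame pair *(t, t+Δ)* the displacement **d** is the subpixel argmax
of the zero-normalized cross-correlation of the window against a search
region of the next frame. The window velocity is the *vector* mean over
pairs, so undirected jitter cancels, and the window speed is

    v_w = | ⟨d⟩ | · pixel_size / (frame_interval · Δ)     [µm/s]

A window is **active** when it lies inside the circular field-of-view mask
(the Transwell), its correlation has a dominant peak, and `v_w` exceeds a
self-calibrated noise floor. Reported: `percent_active` (share of in-FOV
windows active) and `percent_above_threshold` (share with `v_w` above a
reference speed, conventionally the mean speed of active windows pooled over
control movies of the batch, from `compute_control_threshold`).

**Coordination pipeline** (`ciliaflow.coord_stevenage`). Pixels whose
temporal intensity standard deviation exceeds what sensor noise alone would
produce form the **moving mask**. Each moving block of the field gets a flow
direction θ from the same correlation estimator, and its local alignment is
the circular mean resultant length over a disk neighborhood of moving blocks:

    R = | (1/n) Σ_k exp(i·θ_k) | ∈ [0, 1],   E[R] ≈ 0.886/√n under uniform θ

A block is **coordinated** when R ≥ R_min (default 0.8). Reported:
`moving_fraction`, `coordinated_fraction` (both % of FOV area), and
`coordinated_of_moving` (% of the moving area that is coordinated).

**Tracking pipeline** (`ciliaflow.tracking_xenopus`). Laplacian-of-Gaussian
spot detection with subpixel refinement, greedy mutual-nearest-neighbor
linking with gap closing, per-track speed = path length / elapsed time, and
the per-specimen speed = unweighted mean over tracks. Whole-embryo drift is
quantified from the centroid series of the segmented embryo in brightfield
movies (`drift_speed` = net displacement / time, `drift_path_ratio` =
net / total path).

**Simulator** (`ciliaflow.simdata`). Beads rendered as Gaussian spots are
advected by a patchwise flow field with configurable active-area fraction,
per-patch speed, and direction coherence (a mixture of one shared direction
and independent uniform directions); whole-frame drift and a textured
drifting ellipse emulate the embryo assays. Every simulation emits the true
active mask, direction/speed fields, bead tracks, and drift vector.

## Worked example

```python
import numpy as np
from ciliaflow import SimConfig, simulate_transport_movie, run_cambridge, run_stevenage

# half the surface driven at 20 µm/s with fairly coordinated directions
cfg = SimConfig(image_size=(256, 256), n_frames=24, n_beads=1200,
                active_fraction=0.5, coherence=0.9, mean_speed=20.0, seed=1)
movie, truth = simulate_transport_movie(cfg)

piv = run_cambridge(movie, overlap=0.0, fov=1.2, threshold_speed=10.0)
print(f"percent_active          = {piv.percent_active:.1f}")
print(f"percent_above_threshold = {piv.percent_above_threshold:.1f}")

coord = run_stevenage(movie, np.ones(movie.shape, bool))
print(f"moving_fraction         = {coord.moving_fraction:.1f}")
print(f"coordinated_of_moving   = {coord.coordinated_of_moving:.1f}")
```

prints

```
percent_active          = 49.1
percent_above_threshold = 40.4
moving_fraction         = 46.8
coordinated_of_moving   = 69.3
```

The PIV pipeline recovers the configured 50 % active area to within one
window. A handful of active windows straddle patches with discordant
directions, where the vector-mean speed drops below the 10 µm/s threshold —
hence the slightly smaller above-threshold share. The moving mask covers
the swept part of the driven area (46.8 % of the frame), and at coherence
0.9 about 69 % of that moving area is locally aligned.

The same analyses are available from a shell:

```
ciliaflow simulate --out sim --seed 1 --param active_fraction=0.5
ciliaflow piv sim/movie.tif --out piv_results --fov 1.0
ciliaflow coord sim/movie.tif --out coord_results
ciliaflow report piv_results/metrics.csv coord_results/metrics.csv --out summary
```

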