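"""Synthetic bead-movie simulator with ground truth.

Emulates the two kinds of time-lapse acquisitions the quantification
pipelines consume:

* **apical transport assay** — fluorescent tracer beads resting on a
  ciliated epithelial surface, advected by a patchwise flow field.  Only a
  fraction of the surface is actively driven (``active_fraction``); the
  directions of active patches are drawn from a mixture of a shared global
  direction (weight ``coherence``) and independent uniform directions, so
  both the *active area* and the *directional coordination* of the flow are
  exact, known ground truths.
* **embryo drift assay** — a single large textured object (the embryo seen
  in brightfield, dark on a bright background) translating slowly across
  the field of view.

Every simulation emits a :class:`GroundTruth` alongside the rendered
:class:`~ciliaflow.movie_io.MovieStack`, so each downstream metric
(active-area percentage, moving/coordinated fractions, track speeds, drift
velocity) can be validated against a known answer.

The flow model is deliberately simple: piecewise-constant velocity per
patch, no interpolation across patch borders, no Brownian term by default
(``diffusion_sd=0``), constant per-bead brightness and no bleaching.  These
choices keep the ground truth exact; see ``docs/methods.md`` for what that
simplification does and does not let the test-suite conclude about real
movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .movie_io import MovieStack

__all__ = [
    "SimConfig",
    "GroundTruth",
    "build_flow_field",
    "advect_and_render",
    "simulate_transport_movie",
    "simulate_embryo_drift",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic bead movie.

    Defaults mirror the transport-assay acquisition (30 s at 10 frames per
    second) on a 256x256 px field with an 8x8 patch flow field; physical
    calibration (``pixel_size``) is a free choice of the simulation, not a
    measured quantity.
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W) pixels
    n_frames: int = 300
    frame_interval: float = 0.1  # seconds
    pixel_size: float = 1.0  # micrometres per pixel
    n_beads: int = 600
    bead_sigma: float = 1.5  # Gaussian spot width, pixels
    bead_amplitude: float = 80.0  # peak intensity above background
    patch_grid: tuple[int, int] = (8, 8)  # (rows, cols) of flow patches
    active_fraction: float = 1.0
    mean_speed: float = 10.0  # micrometres per second
    speed_cv: float = 0.1
    coherence: float = 1.0
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # (vx, vy) um/s
    diffusion_sd: float = 0.0  # per-frame positional jitter, pixels
    min_separation: float = 0.0  # minimum initial bead spacing, pixels (0 = off)
    background_level: float = 10.0
    noise_sd: float = 2.0
    fov_radius_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        gy, gx = self.patch_grid
        if h < 8 or w < 8:
            raise ValueError("image_size must be at least 8x8 pixels")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if gy < 1 or gx < 1 or gy > h or gx > w:
            raise ValueError("patch_grid must fit inside image_size")
        for name in ("frame_interval", "pixel_size", "bead_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("active_fraction", "coherence", "fov_radius_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_beads < 0 or self.mean_speed < 0 or self.noise_sd < 0:
            raise ValueError("n_beads, mean_speed and noise_sd must be >= 0")

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    @property
    def patch_shape(self) -> tuple[float, float]:
        """Patch extent in pixels (may be fractional)."""
        h, w = self.image_size
        gy, gx = self.patch_grid
        return h / gy, w / gx


@dataclass
class GroundTruth:
    """Simulator-emitted truth channel.

    ``direction_field`` and ``speed_field`` are NaN outside ``active_mask``;
    ``true_tracks`` holds one ``(n, 3)`` float array of ``(frame, x, y)``
    rows per bead, recorded while the bead is inside the frame (frames are
    consecutive, so every track is gap-free and strictly increasing in t).
    """

    active_mask: np.ndarray  # (gy, gx) bool
    direction_field: np.ndarray  # (gy, gx) float radians, NaN if inactive
    speed_field: np.ndarray  # (gy, gx) float um/s, NaN if inactive
    coherence: float
    drift_velocity: tuple[float, float] = (0.0, 0.0)
    true_tracks: list[np.ndarray] = field(default_factory=list)

    def validate(self) -> None:
        active = self.active_mask
        if not np.all(np.isfinite(self.direction_field[active])):
            raise ValueError("direction_field undefined on an active patch")
        if np.any(np.isfinite(self.direction_field[~active])):
            raise ValueError("direction_field defined on an inactive patch")
        for trk in self.true_tracks:
            t = trk[:, 0]
            if len(t) and np.any(np.diff(t) != 1):
                raise ValueError("track frames must be consecutive")


def build_flow_field(
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the patchwise flow field (active mask, directions, speeds).

    The number of active patches is the exact deterministic count
    ``round(active_fraction * n_patches)``; their placement, directions and
    speeds come from ``config.seed``.  Directions are a two-component
    mixture: with probability ``coherence`` a patch adopts the movie-wide
    global direction, otherwise an independent uniform draw on [0, 2pi).
    Speeds are ``mean_speed * (1 + speed_cv * eps)`` with standard-normal
    ``eps``, truncated at zero.
    """
    rng = np.random.default_rng([0, config.seed])
    gy, gx = config.patch_grid
    n_patches = gy * gx
    n_active = int(round(config.active_fraction * n_patches))

    active = np.zeros(n_patches, dtype=bool)
    active[rng.permutation(n_patches)[:n_active]] = True
    active = active.reshape(gy, gx)

    directions = np.full((gy, gx), np.nan)
    speeds = np.full((gy, gx), np.nan)
    global_direction = rng.uniform(0.0, 2.0 * np.pi)
    coherent = rng.random(n_active) < config.coherence
    drawn = np.where(
        coherent, global_direction, rng.uniform(0.0, 2.0 * np.pi, n_active)
    )
    sp = config.mean_speed * (1.0 + config.speed_cv * rng.standard_normal(n_active))
    directions[active] = drawn
    speeds[active] = np.clip(sp, 0.0, None)
    return active, directions, speeds


def _render_frame(
    shape: tuple[int, int],
    positions: np.ndarray,
    alive: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one frame: Gaussian spots + background + sensor noise, uint16."""
    h, w = shape
    img = np.full((h, w), float(config.background_level))
    sigma = config.bead_sigma
    r = max(2, int(np.ceil(4.0 * sigma)))
    for (x, y) in positions[alive]:
        x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
        y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
        cx0, cx1 = max(x0, 0), min(x1, w)
        cy0, cy1 = max(y0, 0), min(y1, h)
        if cx0 >= cx1 or cy0 >= cy1:
            continue
        yy, xx = np.mgrid[cy0:cy1, cx0:cx1]
        img[cy0:cy1, cx0:cx1] += config.bead_amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2)
        )
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def _draw_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform bead positions, with optional minimum spacing (dart throwing)."""
    h, w = config.image_size
    if config.min_separation <= 0:
        return np.column_stack(
            [rng.uniform(0, w, config.n_beads), rng.uniform(0, h, config.n_beads)]
        )
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < config.n_beads:
        if attempts > 200 * config.n_beads:
            raise ValueError(
                "cannot place n_beads with the requested min_separation"
            )
        cand = np.array([rng.uniform(0, w), rng.uniform(0, h)])
        attempts += 1
        if all(
            np.hypot(*(cand - p)) >= config.min_separation for p in accepted
        ):
            accepted.append(cand)
    return np.asarray(accepted)


def advect_and_render(
    config: SimConfig,
    truth: GroundTruth,
    initial_positions: np.ndarray | None = None,
) -> MovieStack:
    """Advect beads through the flow field of ``truth`` and render the movie.

    Each bead moves per frame by its patch velocity (zero in inactive
    patches) plus the whole-frame drift; beads leaving the frame are
    removed from later frames.  Per-bead ``(frame, x, y)`` tracks are
    appended to ``truth.true_tracks``.  Identical config (and seed) gives a
    bit-identical stack.
    """
    h, w = config.image_size
    gy, gx = config.patch_grid
    rng = np.random.default_rng([1, config.seed])

    if initial_positions is None:
        pos = _draw_positions(config, rng)
    else:
        pos = np.asarray(initial_positions, dtype=float).copy()
    n = len(pos)
    alive = np.ones(n, dtype=bool)

    px_per_um = 1.0 / config.pixel_size
    dt = config.frame_interval
    drift_px = np.asarray(config.drift_velocity, float) * dt * px_per_um
    vx = np.nan_to_num(np.cos(truth.direction_field) * truth.speed_field) * dt * px_per_um
    vy = np.nan_to_num(np.sin(truth.direction_field) * truth.speed_field) * dt * px_per_um

    track_pts: list[list[tuple[float, float, float]]] = [[] for _ in range(n)]
    frames = np.empty((config.n_frames, h, w), dtype=np.uint16)
    for t in range(config.n_frames):
        for i in np.flatnonzero(alive):
            track_pts[i].append((float(t), pos[i, 0], pos[i, 1]))
        frames[t] = _render_frame((h, w), pos, alive, config, rng)
        if t == config.n_frames - 1:
            break
        # advance: velocity sampled at the bead's current patch
        py = np.clip((pos[:, 1] * gy / h).astype(int), 0, gy - 1)
        px = np.clip((pos[:, 0] * gx / w).astype(int), 0, gx - 1)
        step = np.column_stack([vx[py, px], vy[py, px]]) + drift_px
        if config.diffusion_sd > 0:
            step += rng.normal(0.0, config.diffusion_sd, size=step.shape)
        pos[alive] += step[alive]
        inside = (
            (pos[:, 0] >= 0) & (pos[:, 0] < w) & (pos[:, 1] >= 0) & (pos[:, 1] < h)
        )
        alive &= inside

    truth.true_tracks.extend(
        np.asarray(p, dtype=float).reshape(-1, 3) for p in track_pts if p
    )
    return MovieStack(
        frames=frames,
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
    )


def simulate_transport_movie(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Full transport-assay simulation: flow field, beads, rendered movie."""
    active, directions, speeds = build_flow_field(config)
    truth = GroundTruth(
        active_mask=active,
        direction_field=directions,
        speed_field=speeds,
        coherence=config.coherence,
        drift_velocity=tuple(config.drift_velocity),
    )
    movie = advect_and_render(config, truth)
    return movie, truth


def _embryo_intensity(
    u: np.ndarray, v: np.ndarray, a: float, b: float
) -> np.ndarray:
    """Textured ellipse profile in object coordinates (1 inside, 0 outside).

    The texture is a fixed sum of incommensurate sinusoids, so the object is
    analytic in its own frame and translates exactly with its centre.
    """
    e = (u / a) ** 2 + (v / b) ** 2
    inside = np.clip((1.0 - e) / 0.08, 0.0, 1.0)  # smooth 8% rim
    texture = 0.75 + 0.12 * np.sin(u / 4.1) * np.cos(v / 5.3) + 0.13 * np.cos(
        u / 9.7 + v / 6.1
    )
    return inside * texture


def simulate_embryo_drift(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a dark textured ellipse drifting across a bright background.

    Brightfield-like contrast: background high, object dark.  The object
    centre starts offset so that the configured drift keeps it fully in
    frame for all ``n_frames``; if that is impossible an error is raised.
    The truth channel records the exact centre series as a single track and
    the drift vector in um/s.
    """
    h, w = config.image_size
    rng = np.random.default_rng([2, config.seed])
    dt = config.frame_interval
    drift_px = np.asarray(config.drift_velocity, float) * dt / config.pixel_size
    a = 0.30 * min(h, w)  # ellipse semi-axes, px
    b = 0.22 * min(h, w)

    total = drift_px * (config.n_frames - 1)
    c0 = np.array([w / 2.0, h / 2.0]) - total / 2.0
    lo = c0 + np.minimum(total, 0.0)
    hi = c0 + np.maximum(total, 0.0)
    if lo[0] - a < 0 or hi[0] + a > w or lo[1] - b < 0 or hi[1] + b > h:
        raise ValueError(
            "drift carries the embryo out of frame before n_frames; "
            "reduce drift_velocity or n_frames, or enlarge image_size"
        )

    background = 180.0
    depth = 130.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.empty((config.n_frames, h, w), dtype=np.uint16)
    centres = np.empty((config.n_frames, 3))
    for t in range(config.n_frames):
        c = c0 + drift_px * t
        img = background - depth * _embryo_intensity(xx - c[0], yy - c[1], a, b)
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, size=img.shape)
        frames[t] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        centres[t] = (t, c[0], c[1])

    gy, gx = config.patch_grid
    truth = GroundTruth(
        active_mask=np.zeros((gy, gx), dtype=bool),
        direction_field=np.full((gy, gx), np.nan),
        speed_field=np.full((gy, gx), np.nan),
        coherence=config.coherence,
        drift_velocity=tuple(config.drift_velocity),
        true_tracks=[centres],
    )
    movie = MovieStack(
        frames=frames,
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
    )
    return movie, truth
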