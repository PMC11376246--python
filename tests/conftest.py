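"""Shared fixtures: small synthetic movies with known flow structure."""

from __future__ import annotations

import numpy as np
import pytest

from ciliaflow.simdata import (
    GroundTruth,
    SimConfig,
    advect_and_render,
    build_flow_field,
)


def make_uniform_flow_movie(
    shift_px_per_frame: float = 2.0,
    direction: float = 0.0,
    n_frames: int = 10,
    n_beads: int = 800,
    bead_sigma: float = 1.2,
    noise_sd: float = 0.0,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 1,
    initial_positions: np.ndarray | None = None,
):
    """Movie in which every bead translates identically; returns (movie, cfg).

    pixel_size=1 um/px and frame_interval=0.1 s, so ``shift_px_per_frame``
    equals mean_speed/10 in um/s.
    """
    cfg = SimConfig(
        image_size=image_size,
        n_frames=n_frames,
        n_beads=n_beads,
        bead_sigma=bead_sigma,
        noise_sd=noise_sd,
        active_fraction=1.0,
        coherence=1.0,
        speed_cv=0.0,
        mean_speed=shift_px_per_frame * 10.0,
        pixel_size=1.0,
        frame_interval=0.1,
        seed=seed,
    )
    active, dirs, speeds = build_flow_field(cfg)
    dirs[:] = direction
    speeds[:] = cfg.mean_speed
    truth = GroundTruth(active, dirs, speeds, coherence=1.0)
    movie = advect_and_render(cfg, truth, initial_positions=initial_positions)
    return movie, truth, cfg


@pytest.fixture(scope="session")
def uniform_flow_movie():
    """Noise-free uniform translation, 2 px/frame along +x."""
    movie, truth, cfg = make_uniform_flow_movie()
    return movie


@pytest.fixture(scope="session")
def static_noisy_movie():
    """Static beads plus sensor noise: nothing genuinely moves."""
    cfg = SimConfig(
        image_size=(256, 256),
        n_frames=16,
        n_beads=1200,
        bead_sigma=1.2,
        noise_sd=2.0,
        active_fraction=0.0,
        mean_speed=20.0,
        seed=0,
    )
    active, dirs, speeds = build_flow_field(cfg)
    truth = GroundTruth(active, dirs, speeds, coherence=cfg.coherence)
    return advect_and_render(cfg, truth)


def tracks_equal(a: np.ndarray, b: np.ndarray, tol_px: float = 0.5) -> bool:
    """Same frames and positions within ``tol_px``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return (
        a.shape == b.shape
        and np.array_equal(a[:, 0], b[:, 0])
        and float(np.abs(a[:, 1:] - b[:, 1:]).max(initial=0.0)) < tol_px
    )


def count_exact_track_matches(true_tracks, linked_tracks, tol_px=0.5) -> int:
    used: set[int] = set()
    n = 0
    for tt in true_tracks:
        for i, lt in enumerate(linked_tracks):
            if i not in used and tracks_equal(tt, lt, tol_px):
                used.add(i)
                n += 1
                break
    return n
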