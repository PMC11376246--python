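"""PIV pipeline: displacement estimation, FOV mask, activity classification."""

import numpy as np
import pytest

from ciliaflow.movie_io import MovieStack
from ciliaflow.piv_cambridge import (
    FlowField,
    classify_active,
    compute_control_threshold,
    compute_piv_field,
    estimate_noise_floor,
    fit_circular_mask,
    fraction_above_threshold,
    run_cambridge,
)
from ciliaflow.simdata import (
    GroundTruth,
    SimConfig,
    advect_and_render,
    build_flow_field,
    simulate_transport_movie,
)

from conftest import make_uniform_flow_movie


def make_field(speeds, valid=None, pixel_size=1.0, frame_interval=0.1):
    """Hand-built FlowField for unit tests of the classification stages."""
    speeds = np.asarray(speeds, dtype=float)
    ny, nx = speeds.shape
    if valid is None:
        valid = np.ones_like(speeds, bool)
    disp = speeds * frame_interval / pixel_size
    return FlowField(
        x=np.arange(nx) * 32.0 + 16.0,
        y=np.arange(ny) * 32.0 + 16.0,
        u=disp,
        v=np.zeros_like(disp),
        speed_um_s=speeds,
        quality=np.full_like(speeds, 2.0),
        valid=np.asarray(valid, bool),
        pair_scatter=np.full_like(speeds, 0.02),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        window_size=32,
        overlap=0.0,
        pair_spacing=1,
        n_pairs=10,
    )


class TestComputePivField:
    def test_uniform_translation_recovered_within_tenth_pixel(self):
        # dense, sharp seeding: the regime PIV is designed for
        movie, _, _ = make_uniform_flow_movie(
            shift_px_per_frame=2.0, n_beads=4000, bead_sigma=0.8
        )
        field = compute_piv_field(movie, window_size=32, overlap=0.5)
        assert field.valid.all()
        assert np.abs(field.u[field.valid] - 2.0).max() < 0.1
        assert np.abs(field.v[field.valid]).max() < 0.1

    def test_static_textured_movie_gives_zero_displacements(self, static_noisy_movie):
        # noise-free static copy: identical frames; displacements vanish up
        # to the pattern-determined subpixel bias, well under the
        # quarter-pixel resolution floor
        frames = np.repeat(static_noisy_movie.frames[:1], 6, axis=0)
        movie = MovieStack(frames, 0.1, 1.0)
        field = compute_piv_field(movie, window_size=32)
        assert field.valid.any()
        assert np.abs(field.u).max() < 0.1 and np.abs(field.v).max() < 0.1
        assert field.speed_um_s.max() < 1.0

    def test_constant_windows_flagged_invalid_with_zero_displacement(self):
        movie = MovieStack(np.full((5, 64, 64), 7, np.uint16), 0.1, 1.0)
        field = compute_piv_field(movie, window_size=32)
        assert not field.valid.any()
        assert (field.u == 0).all() and (field.v == 0).all()

    def test_rotating_the_movie_rotates_the_vector_field(self):
        movie, _, _ = make_uniform_flow_movie(
            shift_px_per_frame=2.0, n_beads=2000, bead_sigma=1.0, n_frames=6
        )
        field = compute_piv_field(movie, window_size=32, overlap=0.0)
        rot = MovieStack(
            np.rot90(movie.frames, 1, axes=(1, 2)).copy(),
            movie.frame_interval,
            movie.pixel_size,
        )
        field_r = compute_piv_field(rot, window_size=32, overlap=0.0)
        # +x flow becomes -y flow under counter-clockwise array rotation
        assert np.abs(field.u[field.valid].mean() - 2.0) < 0.05
        assert np.abs(field_r.v[field_r.valid].mean() + 2.0) < 0.05
        s1 = field.speed_um_s[field.valid].mean()
        s2 = field_r.speed_um_s[field_r.valid].mean()
        assert s2 == pytest.approx(s1, rel=0.01)

    def test_short_movie_rejected(self):
        movie = MovieStack(np.zeros((2, 64, 64)), 0.1, 1.0)
        with pytest.raises(ValueError, match="too short"):
            compute_piv_field(movie, pair_spacing=5)


class TestCircularMask:
    def test_inscribed_circle_area_is_pi_over_4(self):
        movie = MovieStack(np.zeros((2, 200, 200)), 0.1, 1.0)
        mask = fit_circular_mask(movie, 1.0)
        assert mask.mean() == pytest.approx(np.pi / 4, abs=0.01)

    def test_zero_radius_gives_empty_mask_and_downstream_error(self):
        movie = MovieStack(np.zeros((2, 64, 64)), 0.1, 1.0)
        mask = fit_circular_mask(movie, 0.0)
        assert mask.sum() <= 4  # at most the centre pixel(s)
        field = make_field(np.ones((4, 4)))
        with pytest.raises(ValueError, match="in-FOV"):
            classify_active(field, np.zeros((64, 64), bool), 0.1)

    def test_auto_mode_finds_culture_disk_centre(self):
        # vignetted culture: bright disk off-centre on a dark background
        h, w = 160, 200
        yy, xx = np.mgrid[0:h, 0:w]
        disk = ((yy - 85.0) ** 2 + (xx - 90.0) ** 2) <= 60.0**2
        rng = np.random.default_rng(0)
        frames = (
            10.0 + 80.0 * disk + rng.normal(0, 2, size=(4, h, w))
        ).clip(0).astype(np.uint16)
        movie = MovieStack(frames, 0.1, 1.0)
        mask = fit_circular_mask(movie, "auto")
        ys, xs = np.nonzero(mask)
        assert abs(ys.mean() - 85.0) < 2 and abs(xs.mean() - 90.0) < 2

    def test_auto_mode_without_foreground_raises(self):
        movie = MovieStack(np.zeros((2, 64, 64), np.uint16), 0.1, 1.0)
        with pytest.raises(ValueError, match="foreground"):
            fit_circular_mask(movie, "auto")


class TestClassifyActive:
    def test_half_active_simulation_recovers_fifty_percent(self):
        cfg = SimConfig(
            image_size=(256, 256),
            n_frames=16,
            n_beads=1200,
            noise_sd=2.0,
            active_fraction=0.5,
            coherence=0.7,
            bead_sigma=1.2,
            mean_speed=20.0,
            seed=11,
        )
        movie, _ = simulate_transport_movie(cfg)
        field = compute_piv_field(movie, window_size=32, overlap=0.0)
        floor = estimate_noise_floor(field)
        _, pct = classify_active(field, np.ones(movie.shape, bool), floor)
        assert pct == pytest.approx(50.0, abs=5.0)

    def test_static_noisy_movie_is_entirely_inactive(self, static_noisy_movie):
        field = compute_piv_field(static_noisy_movie, window_size=32, overlap=0.0)
        floor = estimate_noise_floor(field)
        _, pct = classify_active(field, np.ones(static_noisy_movie.shape, bool), floor)
        assert pct == 0.0

    def test_invalid_windows_excluded_from_both_sides(self):
        speeds = np.full((4, 4), 10.0)
        valid = np.ones((4, 4), bool)
        valid[0, :] = False
        field = make_field(speeds, valid)
        active, pct = classify_active(field, np.ones((128, 128), bool), 1.0)
        assert pct == 100.0
        assert active.sum() == 12


class TestThresholding:
    def test_threshold_above_everything_gives_zero(self):
        field = make_field(np.full((4, 4), 5.0))
        fov = np.ones((128, 128), bool)
        assert fraction_above_threshold(field, fov, 10.0) == 0.0

    def test_tiny_threshold_equals_percent_active(self):
        field = make_field(np.full((4, 4), 5.0))
        fov = np.ones((128, 128), bool)
        active, pct_active = classify_active(field, fov, 0.5)
        pct_above = fraction_above_threshold(field, fov, 1e-9, active)
        assert pct_above == pct_active == 100.0

    def test_mixed_speed_field_splits_at_intermediate_threshold(self):
        # half the active patches at 2v, half at v/2: threshold v keeps half
        cfg = SimConfig(
            image_size=(256, 256),
            n_frames=16,
            n_beads=1200,
            noise_sd=2.0,
            active_fraction=1.0,
            coherence=1.0,
            speed_cv=0.0,
            bead_sigma=1.2,
            mean_speed=20.0,
            seed=7,
        )
        active, dirs, speeds = build_flow_field(cfg)
        checker = (np.indices(cfg.patch_grid).sum(axis=0) % 2) == 0
        speeds[:] = np.where(checker, 40.0, 10.0)
        truth = GroundTruth(active, dirs, speeds, 1.0)
        movie = advect_and_render(cfg, truth)
        field = compute_piv_field(movie, window_size=32, overlap=0.0)
        fov = np.ones(movie.shape, bool)
        act, pct_active = classify_active(field, fov, estimate_noise_floor(field))
        pct_above = fraction_above_threshold(field, fov, 20.0, act)
        assert pct_above == pytest.approx(pct_active / 2, abs=5.0)

    def test_nesting_always_holds(self):
        rng = np.random.default_rng(3)
        field = make_field(rng.uniform(0, 10, size=(5, 5)))
        fov = np.ones((160, 160), bool)
        active, pct_active = classify_active(field, fov, 1.0)
        for thr in (1.0, 2.5, 5.0, 9.0):
            assert fraction_above_threshold(field, fov, thr, active) <= pct_active


class TestControlThreshold:
    def test_single_uniform_control_returns_its_speed(self):
        field = make_field(np.full((4, 4), 7.0))
        active = np.ones((4, 4), bool)
        assert compute_control_threshold([(field, active)]) == pytest.approx(7.0)

    def test_two_controls_average_arithmetically(self):
        f1 = make_field(np.full((4, 4), 5.0))
        f2 = make_field(np.full((4, 4), 15.0))
        a = np.ones((4, 4), bool)
        assert compute_control_threshold([(f1, a), (f2, a)]) == pytest.approx(10.0)

    def test_no_active_windows_raises(self):
        field = make_field(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="threshold undefined"):
            compute_control_threshold([(field, np.zeros((4, 4), bool))])

    def test_simulated_control_batch_recovers_mean_speed(self):
        controls = []
        for seed in range(2):
            cfg = SimConfig(
                image_size=(256, 256),
                n_frames=16,
                n_beads=1200,
                noise_sd=2.0,
                active_fraction=1.0,
                coherence=1.0,
                speed_cv=0.1,
                bead_sigma=1.2,
                mean_speed=20.0,
                seed=seed,
            )
            movie, _ = simulate_transport_movie(cfg)
            field = compute_piv_field(movie, window_size=32, overlap=0.0)
            act, _ = classify_active(
                field, np.ones(movie.shape, bool), estimate_noise_floor(field)
            )
            controls.append((field, act))
        thr = compute_control_threshold(controls)
        assert thr == pytest.approx(20.0, rel=0.05)


class TestSpeedScaleEquivariance:
    def test_doubling_speed_doubles_recovery_and_keeps_activity(self):
        results = {}
        for ms in (10.0, 20.0):
            cfg = SimConfig(
                image_size=(192, 192),
                patch_grid=(6, 6),
                n_frames=12,
                n_beads=900,
                noise_sd=2.0,
                active_fraction=0.5,
                coherence=1.0,
                speed_cv=0.0,
                bead_sigma=1.2,
                mean_speed=ms,
                seed=5,
            )
            movie, _ = simulate_transport_movie(cfg)
            field = compute_piv_field(movie, window_size=32, overlap=0.0)
            act, pct = classify_active(
                field, np.ones(movie.shape, bool), estimate_noise_floor(field)
            )
            results[ms] = (field.speed_um_s[act].mean(), pct)
        assert results[20.0][0] == pytest.approx(2 * results[10.0][0], rel=0.05)
        assert results[20.0][1] == pytest.approx(results[10.0][1], abs=5.0)


def test_run_cambridge_end_to_end():
    cfg = SimConfig(
        image_size=(192, 192),
        patch_grid=(6, 6),
        n_frames=12,
        n_beads=900,
        noise_sd=2.0,
        active_fraction=0.5,
        coherence=1.0,
        bead_sigma=1.2,
        mean_speed=20.0,
        seed=8,
    )
    movie, _ = simulate_transport_movie(cfg)
    res = run_cambridge(movie, overlap=0.0, fov=1.2, threshold_speed=10.0)
    assert 0 <= res.percent_above_threshold <= res.percent_active <= 100
    rows = res.metrics("m1", "NT")
    assert set(rows["metric"]) == {
        "percent_active",
        "percent_above_threshold",
        "threshold_speed",
    }
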