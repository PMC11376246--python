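"""PIV-based quantification of bead transport ("percent active" pipeline).

The pipeline estimates a flow velocity vector field by normalized
cross-correlation of interrogation windows between frame pairs, restricts
attention to a circular field-of-view mask (the Transwell insert), then
classifies each window as *active* (time-averaged speed above a noise
floor) and as *above threshold* (speed above an externally supplied
reference, by convention the mean speed of active windows pooled over
control movies of the same batch).  The two headline metrics are the
percentage of in-FOV windows that are active and the percentage above
threshold.

Temporal aggregation is a vector mean over frame pairs — incoherent jitter
cancels, so window speed measures *directed* transport, which is what the
assay is after.  Windows whose correlation plane has no dominant peak
(first-to-second peak ratio below ``min_quality``) are excluded from both
the numerator and the denominator of every percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .movie_io import MovieStack

__all__ = [
    "FlowField",
    "CambridgeResult",
    "compute_piv_field",
    "fit_circular_mask",
    "estimate_noise_floor",
    "classify_active",
    "fraction_above_threshold",
    "compute_control_threshold",
    "run_cambridge",
]

_EPS = 1e-12


@dataclass
class FlowField:
    """Per-window velocity field.

    ``u``/``v`` are the vector-mean displacements in pixels per
    ``pair_spacing`` frames (x = column, y = row, y down); ``speed_um_s``
    is their magnitude converted to micrometres per second;
    ``quality`` is the median first-to-second correlation peak ratio and
    ``valid`` marks windows with a trustworthy estimate.
    """

    x: np.ndarray  # (nx,) window-centre columns, px
    y: np.ndarray  # (ny,) window-centre rows, px
    u: np.ndarray  # (ny, nx) px / pair
    v: np.ndarray  # (ny, nx)
    speed_um_s: np.ndarray  # (ny, nx)
    quality: np.ndarray  # (ny, nx)
    valid: np.ndarray  # (ny, nx) bool
    pair_scatter: np.ndarray  # (ny, nx) per-component SD of pair displacements, px
    pixel_size: float
    frame_interval: float
    window_size: int
    overlap: float
    pair_spacing: int
    n_pairs: int

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
                "speed_um_s": self.speed_um_s.ravel(),
                "quality": self.quality.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def _pair_displacements(
    a: np.ndarray, b_ext: np.ndarray, max_disp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Displacement of the next frame relative to a batch of windows.

    ``a``: (ny, nx, w, w) interrogation windows of the first frame;
    ``b_ext``: (ny, nx, w + 2m, w + 2m) search regions of the second frame
    centred on the same windows (m = ``max_disp``), so that matched
    content never truncates at the window border — template-style
    normalized cross-correlation rather than circular windowed
    correlation, which removes the edge-truncation bias.  Returns
    (dx, dy, peak_ratio, pair_valid), each (ny, nx).  The displacement is
    the subpixel-refined argmax searched within +-``max_disp``;
    zero-variance windows are flagged invalid with zero displacement.
    """
    w = a.shape[-1]
    m = max_disp
    S = w + 2 * m
    a0 = a - a.mean(axis=(-2, -1), keepdims=True)
    na = np.sqrt((a0**2).sum(axis=(-2, -1)))
    nb = np.std(b_ext, axis=(-2, -1))
    pair_valid = (na > _EPS) & (nb > _EPS)

    # zero-normalized cross-correlation (ZNCC): the numerator is the
    # zero-padded linear correlation of the zero-mean template with the
    # search region (lags 0..2m are exact); the denominator normalizes by
    # the local energy of the search region under the template support at
    # each lag, computed with a box kernel.  Local normalization keeps the
    # correlation bounded and removes the bias that unmatched content in
    # the search margin otherwise exerts on the subpixel peak fit.
    fa = np.fft.rfft2(a0, s=(S, S))
    fb = np.fft.rfft2(b_ext, s=(S, S))
    fones = np.fft.rfft2(np.ones((w, w)), s=(S, S))
    num = np.fft.irfft2(np.conj(fa) * fb, s=(S, S))[..., : 2 * m + 1, : 2 * m + 1]
    sb = np.fft.irfft2(np.conj(fones) * fb, s=(S, S))[..., : 2 * m + 1, : 2 * m + 1]
    fb2 = np.fft.rfft2(b_ext**2, s=(S, S))
    sb2 = np.fft.irfft2(np.conj(fones) * fb2, s=(S, S))[..., : 2 * m + 1, : 2 * m + 1]
    energy = np.clip(sb2 - sb**2 / (w * w), 0.0, None)
    denom = np.sqrt(energy) * na[..., None, None]
    sub = num / np.maximum(denom, _EPS)
    ny, nx, sh, sw = sub.shape
    flat = sub.reshape(ny, nx, -1)
    idx = flat.argmax(axis=-1)
    iy, ix = np.divmod(idx, sw)
    p1 = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    cmin = flat.min(axis=-1)

    # second peak outside a 3x3 exclusion zone around the first
    masked = sub.copy()
    gy, gx = np.ogrid[0:sh, 0:sw]
    excl = (np.abs(gy[None, None] - iy[..., None, None]) <= 1) & (
        np.abs(gx[None, None] - ix[..., None, None]) <= 1
    )
    masked[excl] = -np.inf
    p2 = masked.reshape(ny, nx, -1).max(axis=-1)
    ratio = (p1 - cmin) / np.maximum(p2 - cmin, _EPS)
    ratio = np.where(np.isfinite(ratio), ratio, np.inf)

    def _subpixel(i, axis):
        on_edge = (i == 0) | (i == (sh if axis == 0 else sw) - 1)
        i_m = np.clip(i - 1, 0, None)
        i_p = np.clip(i + 1, 0, (sh if axis == 0 else sw) - 1)
        if axis == 0:
            c0 = sub[np.arange(ny)[:, None], np.arange(nx)[None, :], i, ix]
            cm = sub[np.arange(ny)[:, None], np.arange(nx)[None, :], i_m, ix]
            cp = sub[np.arange(ny)[:, None], np.arange(nx)[None, :], i_p, ix]
        else:
            c0 = sub[np.arange(ny)[:, None], np.arange(nx)[None, :], iy, i]
            cm = sub[np.arange(ny)[:, None], np.arange(nx)[None, :], iy, i_m]
            cp = sub[np.arange(ny)[:, None], np.arange(nx)[None, :], iy, i_p]
        # 3-point Gaussian fit on raw correlation values (positive near the
        # peak after mean subtraction); parabolic fallback otherwise
        pos_ok = (cm > _EPS) & (c0 > _EPS) & (cp > _EPS)
        with np.errstate(all="ignore"):
            lm = np.log(np.where(pos_ok, cm, 1.0))
            l0 = np.log(np.where(pos_ok, c0, 1.0))
            lp = np.log(np.where(pos_ok, cp, 1.0))
            dg = lm - 2 * l0 + lp
            delta_g = np.where(np.abs(dg) > _EPS, 0.5 * (lm - lp) / dg, 0.0)
            dp_ = cm - 2 * c0 + cp
            delta_p = np.where(np.abs(dp_) > _EPS, 0.5 * (cm - cp) / dp_, 0.0)
        delta = np.where(pos_ok, delta_g, delta_p)
        delta = np.clip(np.nan_to_num(delta), -1.0, 1.0)
        return np.where(on_edge, 0.0, delta)

    dy = iy + _subpixel(iy, axis=0) - m
    dx = ix + _subpixel(ix, axis=1) - m
    dx = np.where(pair_valid, dx, 0.0)
    dy = np.where(pair_valid, dy, 0.0)
    ratio = np.where(pair_valid, ratio, 0.0)
    return dx, dy, ratio, pair_valid


def _window_grid(
    shape: tuple[int, int], window_size: int, overlap: float
) -> tuple[np.ndarray, np.ndarray, int]:
    h, w = shape
    step = max(1, int(round(window_size * (1.0 - overlap))))
    x0 = np.arange(0, w - window_size + 1, step)
    y0 = np.arange(0, h - window_size + 1, step)
    return x0, y0, step


def compute_piv_field(
    movie: MovieStack,
    window_size: int = 32,
    overlap: float = 0.5,
    pair_spacing: int = 1,
    max_disp: int | None = None,
    min_quality: float = 1.1,
) -> FlowField:
    """Estimate the per-window flow field of a movie.

    For every window and every frame pair ``(t, t + pair_spacing)`` the
    displacement is the subpixel argmax of the normalized cross-correlation
    of the two windows; the per-window velocity is the vector mean over
    pairs, and the window speed (um/s) is the magnitude of that mean.
    """
    if window_size < 8:
        raise ValueError("window_size must be >= 8 px")
    if movie.n_frames < pair_spacing + 1:
        raise ValueError("movie too short for the requested pair_spacing")
    if max_disp is None:
        max_disp = window_size // 3

    frames = movie.frames.astype(np.float64)
    x0, y0, step = _window_grid(movie.shape, window_size, overlap)
    n_pairs = movie.n_frames - pair_spacing

    sum_dx = sum_dy = sum_dx2 = sum_dy2 = None
    n_valid = None
    ratios = []
    S = window_size + 2 * max_disp
    for t in range(n_pairs):
        wa = sliding_window_view(frames[t], (window_size, window_size))[::step, ::step]
        padded = np.pad(frames[t + pair_spacing], max_disp)
        wb = sliding_window_view(padded, (S, S))[::step, ::step]
        wa = wa[: len(y0), : len(x0)]
        wb = wb[: len(y0), : len(x0)]
        dx, dy, ratio, pv = _pair_displacements(wa, wb, max_disp)
        if sum_dx is None:
            sum_dx = np.zeros_like(dx)
            sum_dy = np.zeros_like(dy)
            sum_dx2 = np.zeros_like(dx)
            sum_dy2 = np.zeros_like(dy)
            n_valid = np.zeros(dx.shape, dtype=int)
        sum_dx += np.where(pv, dx, 0.0)
        sum_dy += np.where(pv, dy, 0.0)
        sum_dx2 += np.where(pv, dx**2, 0.0)
        sum_dy2 += np.where(pv, dy**2, 0.0)
        n_valid += pv
        ratios.append(np.where(pv, ratio, np.nan))

    denom = np.maximum(n_valid, 1)
    u = sum_dx / denom
    v = sum_dy / denom
    var = np.clip(sum_dx2 / denom - u**2, 0, None) + np.clip(
        sum_dy2 / denom - v**2, 0, None
    )
    pair_scatter = np.sqrt(var / 2.0)  # per-component SD of pair displacements
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        quality = np.nanmedian(np.stack(ratios), axis=0)
    quality = np.nan_to_num(quality, nan=0.0)
    valid = (n_valid >= max(1, n_pairs // 2)) & (quality >= min_quality)
    speed = (
        np.hypot(u, v) * movie.pixel_size / (movie.frame_interval * pair_spacing)
    )
    return FlowField(
        x=x0 + window_size / 2.0,
        y=y0 + window_size / 2.0,
        u=u,
        v=v,
        speed_um_s=speed,
        quality=quality,
        valid=valid,
        pair_scatter=pair_scatter,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        window_size=window_size,
        overlap=overlap,
        pair_spacing=pair_spacing,
        n_pairs=n_pairs,
    )


def fit_circular_mask(
    movie: MovieStack, radius_fraction: float | str = 1.0
) -> np.ndarray:
    """Boolean circular field-of-view mask.

    With a numeric ``radius_fraction`` the circle is centred with radius
    ``radius_fraction * min(H, W) / 2`` (values above 1 are allowed and
    simply cover more of the frame, up to the whole of it).  With
    ``"auto"`` the circle is fitted to the bright culture area of the
    temporal-mean image: Otsu threshold, largest connected component,
    enclosing circle around its centroid.
    """
    h, w = movie.shape
    yy, xx = np.ogrid[0:h, 0:w]
    if isinstance(radius_fraction, str):
        if radius_fraction != "auto":
            raise ValueError("radius_fraction must be a number or 'auto'")
        tmean = movie.frames.mean(axis=0)
        thr = threshold_otsu(tmean)
        fg = tmean > thr
        labels, n = ndi.label(fg)
        if n == 0:
            raise ValueError("auto FOV: no foreground component found")
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        comp = labels == (1 + int(np.argmax(sizes)))
        cy, cx = ndi.center_of_mass(comp)
        ys, xs = np.nonzero(comp)
        radius = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2).max()
    else:
        if radius_fraction < 0:
            raise ValueError("radius_fraction must be >= 0")
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        radius = radius_fraction * min(h, w) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def estimate_noise_floor(
    field: FlowField,
    scatter_percentile: float = 90.0,
    safety: float = 2.0,
    resolution_px: float = 0.25,
) -> float:
    """Self-calibrated speed noise floor (um/s) from temporal jitter.

    Two noise terms are combined and the larger wins:

    * **jitter null** — under no directed transport a window's per-pair
      displacements are zero-mean with per-component SD sigma, so the
      magnitude of their vector mean is Rayleigh with scale
      ``sigma / sqrt(n_pairs)`` (95th percentile ``2.448 * sigma /
      sqrt(n_pairs)``); sigma is pooled conservatively as the
      ``scatter_percentile`` of per-window pair scatter and multiplied by
      ``safety``.
    * **resolution floor** — a fixed ``resolution_px`` per frame pair
      (quarter pixel by default): a static texture produces a small
      pattern-determined subpixel bias that repeats every pair and is
      therefore invisible to the jitter term; displacements below a
      quarter pixel per pair cannot be certified as directed motion.

    A static-but-noisy movie classifies as entirely inactive, while
    genuinely advected windows clear the floor easily.  Needs at least two
    frame pairs.
    """
    if field.n_pairs < 2:
        raise ValueError("noise floor needs >= 2 frame pairs; pass one explicitly")
    scatter = field.pair_scatter[field.valid]
    if scatter.size == 0:
        scatter = field.pair_scatter.ravel()
    sigma = float(np.percentile(scatter, scatter_percentile))
    rayleigh_q95 = np.sqrt(-2.0 * np.log(0.05))
    floor_px = max(
        safety * rayleigh_q95 * sigma / np.sqrt(field.n_pairs), resolution_px
    )
    floor = floor_px * field.pixel_size / (field.frame_interval * field.pair_spacing)
    return max(float(floor), _EPS)


def _in_fov(field: FlowField, fov_mask: np.ndarray) -> np.ndarray:
    """Windows whose centre lies inside the field-of-view mask."""
    iy = np.clip(np.round(field.y).astype(int), 0, fov_mask.shape[0] - 1)
    ix = np.clip(np.round(field.x).astype(int), 0, fov_mask.shape[1] - 1)
    return fov_mask[np.ix_(iy, ix)]


def classify_active(
    field: FlowField, fov_mask: np.ndarray, noise_floor: float
) -> tuple[np.ndarray, float]:
    """Active-window mask and the percentage of in-FOV windows active.

    A window is active iff it is in the FOV, its correlation is valid, and
    its time-averaged speed exceeds ``noise_floor`` (um/s).  Invalid
    windows are excluded from the denominator as well.
    """
    considered = _in_fov(field, fov_mask) & field.valid
    if not considered.any():
        raise ValueError("no valid in-FOV windows; cannot compute percent_active")
    active = considered & (field.speed_um_s > noise_floor)
    return active, 100.0 * active.sum() / considered.sum()


def fraction_above_threshold(
    field: FlowField,
    fov_mask: np.ndarray,
    threshold_speed: float,
    active_mask: np.ndarray | None = None,
) -> float:
    """Percent of in-FOV window area with speed above ``threshold_speed``.

    When ``active_mask`` is given, above-threshold windows are restricted
    to active ones, which guarantees the nesting
    percent_above_threshold <= percent_active.
    """
    considered = _in_fov(field, fov_mask) & field.valid
    if not considered.any():
        raise ValueError("no valid in-FOV windows")
    above = considered & (field.speed_um_s > threshold_speed)
    if active_mask is not None:
        above &= active_mask
    return 100.0 * above.sum() / considered.sum()


def compute_control_threshold(
    controls: list[tuple[FlowField, np.ndarray]]
) -> float:
    """Mean speed over active in-FOV windows pooled across control movies.

    ``controls`` holds ``(field, active_mask)`` pairs from
    :func:`classify_active` on each control movie of the batch.  Pooling is
    over windows (each active window contributes once), matching a
    "mean control speed" reference restricted to moving area.
    """
    speeds = [f.speed_um_s[a] for f, a in controls]
    pooled = np.concatenate(speeds) if speeds else np.array([])
    if pooled.size == 0:
        raise ValueError("no active control windows; threshold undefined")
    return float(pooled.mean())


@dataclass
class CambridgeResult:
    """Bundle of all PIV-pipeline outputs for one movie."""

    field: FlowField
    fov_mask: np.ndarray
    active_mask: np.ndarray
    above_threshold_mask: np.ndarray | None
    percent_active: float
    percent_above_threshold: float | None
    threshold_speed: float | None
    noise_floor: float

    def metrics(self, movie_id: str = "", group: str = "") -> pd.DataFrame:
        rows = [
            (movie_id, group, "piv", "percent_active", self.percent_active),
        ]
        if self.percent_above_threshold is not None:
            rows.append(
                (movie_id, group, "piv", "percent_above_threshold",
                 self.percent_above_threshold)
            )
            rows.append((movie_id, group, "piv", "threshold_speed", self.threshold_speed))
        return pd.DataFrame(
            rows, columns=["movie_id", "group", "pipeline", "metric", "value"]
        )


def run_cambridge(
    movie: MovieStack,
    window_size: int = 32,
    overlap: float = 0.5,
    pair_spacing: int = 1,
    fov: float | str | np.ndarray = 1.0,
    noise_floor: float | str = "auto",
    threshold_speed: float | None = None,
    min_quality: float = 1.1,
) -> CambridgeResult:
    """Run the full PIV pipeline on one movie."""
    field = compute_piv_field(
        movie,
        window_size=window_size,
        overlap=overlap,
        pair_spacing=pair_spacing,
        min_quality=min_quality,
    )
    if isinstance(fov, np.ndarray):
        fov_mask = fov.astype(bool)
    else:
        fov_mask = fit_circular_mask(movie, fov)
    if noise_floor == "auto":
        noise_floor = estimate_noise_floor(field)
    active_mask, percent_active = classify_active(field, fov_mask, float(noise_floor))
    above = percent_above = None
    if threshold_speed is not None:
        percent_above = fraction_above_threshold(
            field, fov_mask, threshold_speed, active_mask
        )
        above = (
            _in_fov(field, fov_mask)
            & field.valid
            & active_mask
            & (field.speed_um_s > threshold_speed)
        )
    return CambridgeResult(
        field=field,
        fov_mask=fov_mask,
        active_mask=active_mask,
        above_threshold_mask=above,
        percent_active=percent_active,
        percent_above_threshold=percent_above,
        threshold_speed=threshold_speed,
        noise_floor=float(noise_floor),
    )
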