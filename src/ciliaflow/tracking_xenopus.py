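"""Bead tracking and whole-embryo drift quantification.

Surface beads on embryos are detected per frame as local maxima of a
Laplacian-of-Gaussian response with subpixel refinement, linked into
trajectories by greedy mutual-nearest-neighbor assignment with gap
closing, and summarized as per-track and per-specimen mean speeds.
Whole-embryo drift is quantified from the centroid series of the
segmented embryo in brightfield movies: drift speed (net displacement
over elapsed time) and drift path ratio (net over total path length,
1 for straight-line drift, near 0 for wandering that returns to start).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .movie_io import MovieStack, tracks_to_frame

__all__ = [
    "TrackSet",
    "DriftResult",
    "detect_beads",
    "link_tracks",
    "specimen_speed",
    "embryo_drift",
]


def detect_beads(
    movie: MovieStack,
    spot_sigma: float = 1.5,
    snr_min: float = 5.0,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in every frame.

    Candidates are local maxima of the scale-normalized negated
    Laplacian-of-Gaussian response at ``spot_sigma`` whose response
    exceeds ``median + snr_min * sigma_MAD`` of the response plane;
    positions are refined to subpixel precision by a per-axis quadratic
    fit.  Detections with another detection within ``2.5 * spot_sigma``
    are flagged ``crowded`` (possible merges).  Returns a tidy frame with
    columns frame, x, y, response, crowded; empty frames contribute no
    rows.
    """
    rows = []
    size = max(3, 2 * int(np.ceil(spot_sigma)) + 1)
    for t in range(movie.n_frames):
        frame = movie.frames[t].astype(np.float64)
        resp = -(spot_sigma**2) * ndi.gaussian_laplace(frame, spot_sigma)
        med = np.median(resp)
        mad = 1.4826 * np.median(np.abs(resp - med))
        thr = med + snr_min * max(mad, 1e-9)
        peaks = (resp == ndi.maximum_filter(resp, size=size)) & (resp > thr)
        peaks[0, :] = peaks[-1, :] = False
        peaks[:, 0] = peaks[:, -1] = False
        ys, xs = np.nonzero(peaks)
        pts = []
        for y, x in zip(ys, xs):
            # quadratic subpixel per axis on the LoG response
            def delta(cm, c0, cp):
                d = cm - 2 * c0 + cp
                return 0.5 * (cm - cp) / d if abs(d) > 1e-12 else 0.0

            dx = delta(resp[y, x - 1], resp[y, x], resp[y, x + 1])
            dy = delta(resp[y - 1, x], resp[y, x], resp[y + 1, x])
            pts.append((x + np.clip(dx, -1, 1), y + np.clip(dy, -1, 1), resp[y, x]))
        if not pts:
            continue
        pts = np.asarray(pts)
        crowded = np.zeros(len(pts), dtype=bool)
        if len(pts) > 1:
            tree = cKDTree(pts[:, :2])
            pairs = tree.query_pairs(2.5 * spot_sigma)
            for i, j in pairs:
                crowded[i] = crowded[j] = True
        for (x, y, r), c in zip(pts, crowded):
            rows.append((t, x, y, r, c))
    return pd.DataFrame(rows, columns=["frame", "x", "y", "response", "crowded"])


class TrackSet:
    """Linked bead trajectories.

    Each track is an ``(n, 3)`` float array of (frame, x_px, y_px) rows
    with strictly increasing frames.
    """

    def __init__(self, tracks, max_displacement, min_track_length, max_gap=2):
        self.tracks = [np.asarray(t, dtype=float).reshape(-1, 3) for t in tracks]
        self.max_displacement = max_displacement
        self.min_track_length = min_track_length
        self.max_gap = max_gap
        for trk in self.tracks:
            if np.any(np.diff(trk[:, 0]) <= 0):
                raise ValueError("track frames must strictly increase")

    def __len__(self) -> int:
        return len(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        return tracks_to_frame(self.tracks)


def link_tracks(
    detections: pd.DataFrame,
    max_displacement: float = 10.0,
    min_track_length: int = 3,
    max_gap: int = 2,
) -> TrackSet:
    """Link per-frame detections into tracks.

    Greedy mutual-nearest-neighbor assignment: candidate (track, detection)
    pairs within the displacement cutoff are accepted in order of
    increasing distance, each endpoint at most once — equivalent to
    repeatedly matching mutual nearest neighbors.  A track left unmatched
    stays open for up to ``max_gap`` frames (gap closing), with the
    cutoff scaled by the number of skipped steps.  Tracks with fewer than
    ``min_track_length`` points are discarded.
    """
    if detections.empty:
        return TrackSet([], max_displacement, min_track_length, max_gap)
    open_tracks: list[dict] = []
    closed: list[list] = []
    t0, t1 = int(detections["frame"].min()), int(detections["frame"].max())
    by_frame = dict(tuple(detections.groupby("frame")))
    for t in range(t0, t1 + 1):
        det = by_frame.get(t)
        pts = (
            det[["x", "y"]].to_numpy(dtype=float)
            if det is not None
            else np.empty((0, 2))
        )
        # match in rounds of increasing staleness: direct frame-to-frame
        # links strictly outrank gap-closing links, so a stale track can
        # never steal a detection from a track seen in the previous frame
        used_t: set[int] = set()
        used_d: set[int] = set()
        for steps in range(1, max_gap + 2):
            cands = []
            for ti, trk in enumerate(open_tracks):
                if ti in used_t or t - trk["last_frame"] != steps:
                    continue
                last = trk["points"][-1]
                for di in range(len(pts)):
                    if di in used_d:
                        continue
                    d = np.hypot(pts[di, 0] - last[1], pts[di, 1] - last[2])
                    if d <= max_displacement * steps:
                        cands.append((d, ti, di))
            cands.sort()
            for _, ti, di in cands:
                if ti in used_t or di in used_d:
                    continue
                used_t.add(ti)
                used_d.add(di)
                open_tracks[ti]["points"].append((float(t), pts[di, 0], pts[di, 1]))
                open_tracks[ti]["last_frame"] = t
        for di in range(len(pts)):
            if di not in used_d:
                open_tracks.append(
                    {"points": [(float(t), pts[di, 0], pts[di, 1])], "last_frame": t}
                )
        # retire tracks whose gap allowance is exhausted
        still_open = []
        for trk in open_tracks:
            if t - trk["last_frame"] > max_gap:
                closed.append(trk["points"])
            else:
                still_open.append(trk)
        open_tracks = still_open
    closed.extend(trk["points"] for trk in open_tracks)
    kept = [p for p in closed if len(p) >= min_track_length]
    kept.sort(key=lambda p: (p[0][0], p[0][1], p[0][2]))
    return TrackSet(kept, max_displacement, min_track_length, max_gap)


def specimen_speed(
    trackset: TrackSet,
    pixel_size: float,
    frame_interval: float,
) -> tuple[float, pd.DataFrame]:
    """Per-specimen mean track speed (um/s) and the per-track table.

    Per-track speed is total path length over elapsed time (matching the
    track-speed semantics of common spot trackers); a net-displacement
    speed is also reported per track.  The specimen speed is the
    unweighted arithmetic mean of its tracks' path speeds.
    """
    if len(trackset) == 0:
        raise ValueError("empty TrackSet: per-specimen speed undefined")
    rows = []
    for tid, trk in enumerate(trackset.tracks):
        steps = np.diff(trk[:, 1:3], axis=0)
        path_px = np.hypot(steps[:, 0], steps[:, 1]).sum()
        n_steps = trk[-1, 0] - trk[0, 0]
        net_px = np.hypot(*(trk[-1, 1:3] - trk[0, 1:3]))
        elapsed = n_steps * frame_interval
        rows.append(
            (
                tid,
                len(trk),
                path_px * pixel_size / elapsed if elapsed > 0 else 0.0,
                net_px * pixel_size / elapsed if elapsed > 0 else 0.0,
            )
        )
    per_track = pd.DataFrame(
        rows, columns=["track_id", "n_points", "speed_um_s", "net_speed_um_s"]
    )
    return float(per_track["speed_um_s"].mean()), per_track


@dataclass
class DriftResult:
    """Whole-specimen drift from a centroid series."""

    centroid_series: pd.DataFrame  # frame, cx, cy (pixels)
    drift_speed: float  # um/s, |net displacement| / elapsed time
    drift_path_ratio: float  # net / total path, in [0, 1]
    drift_vector: tuple[float, float]  # um/s


def embryo_drift(
    movie: MovieStack,
    object_polarity: str = "dark",
    min_area: int = 50,
) -> DriftResult:
    """Quantify slow directional movement of a single large object.

    Each frame is segmented by an Otsu threshold (object darker than
    background by default; ``object_polarity="bright"`` flips this), the
    largest connected component above ``min_area`` is taken as the
    specimen and its centroid recorded.  Drift speed is net displacement
    over elapsed time; the path ratio is net over total path length (0
    when the total path is zero).
    """
    centroids = []
    for t in range(movie.n_frames):
        frame = movie.frames[t].astype(np.float64)
        if np.ptp(frame) <= 0:
            raise ValueError(f"no object found in frame {t} (constant image)")
        thr = threshold_otsu(frame)
        obj = frame < thr if object_polarity == "dark" else frame > thr
        labels, n = ndi.label(obj)
        if n == 0:
            raise ValueError(f"no object found in frame {t}")
        sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        if sizes.max() < min_area:
            raise ValueError(f"no object of at least {min_area} px in frame {t}")
        comp = labels == (1 + int(np.argmax(sizes)))
        cy, cx = ndi.center_of_mass(comp)
        centroids.append((t, cx, cy))
    series = pd.DataFrame(centroids, columns=["frame", "cx", "cy"])
    xy = series[["cx", "cy"]].to_numpy()
    net = np.hypot(*(xy[-1] - xy[0]))
    steps = np.diff(xy, axis=0)
    total = np.hypot(steps[:, 0], steps[:, 1]).sum()
    elapsed = movie.duration
    vec = (xy[-1] - xy[0]) * movie.pixel_size / elapsed
    return DriftResult(
        centroid_series=series,
        drift_speed=float(net * movie.pixel_size / elapsed),
        drift_path_ratio=float(net / total) if total > 0 else 0.0,
        drift_vector=(float(vec[0]), float(vec[1])),
    )
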