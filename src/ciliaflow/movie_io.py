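"""Movie, mask, table and manifest I/O.

One coordinate convention holds package-wide: pixel indices are 0-based,
``x`` is the column, ``y`` the row, origin at the top-left, so ``y``
increases downwards and angles from ``atan2(vy, vx)`` are measured
clockwise when the image is displayed.  All CSV outputs are in pixels;
conversion to physical units happens at metric time using the calibration
carried by :class:`MovieStack` and recorded in the :class:`RunManifest`.

Calibration precedence on read: explicit arguments beat TIFF metadata beat
error — movies never get silent default calibrations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("ciliaflow")

__all__ = [
    "MovieStack",
    "RunManifest",
    "read_movie",
    "write_movie",
    "write_mask",
    "read_mask",
    "tracks_to_frame",
    "write_outputs",
    "sha256_of",
]


@dataclass
class MovieStack:
    """A calibrated T x H x W intensity stack.

    ``frame_interval`` is in seconds, ``pixel_size`` in micrometres per
    pixel.  Frames must share one shape and there must be at least two of
    them (every pipeline needs at least one frame pair).
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frames.shape[0] < 2:
            raise ValueError("need >= 2 frames")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")
        if np.issubdtype(self.frames.dtype, np.floating) and np.any(
            self.frames < 0
        ):
            raise ValueError("frame intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Elapsed time first-to-last frame, seconds."""
        return (self.n_frames - 1) * self.frame_interval


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a 16-bit multi-page TIFF with ImageJ-style calibration metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = movie.frames
    if not np.issubdtype(data.dtype, np.unsignedinteger):
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data.astype(np.uint16),
        imagej=True,
        resolution=(1.0 / movie.pixel_size, 1.0 / movie.pixel_size),
        metadata={"axes": "TYX", "finterval": movie.frame_interval, "unit": "um"},
    )
    return path


def _calibration_from_tiff(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    interval = None
    pixel = None
    meta = tif.imagej_metadata or {}
    if "finterval" in meta:
        interval = float(meta["finterval"])
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is not None:
        num, den = tag.value
        if num:
            pixel = den / num
    return interval, pixel


def read_movie(
    path: str | Path,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
) -> MovieStack:
    """Read a multi-page TIFF (or a directory of numbered single-page TIFFs).

    Explicit ``frame_interval`` / ``pixel_size`` override any metadata (with
    a logged warning if they disagree); when neither source supplies a
    value, an error is raised rather than assuming a default.
    """
    path = Path(path)
    meta_interval = meta_pixel = None
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise ValueError(f"no TIFF files in directory {path}")
        frames = np.stack([tifffile.imread(f) for f in files])
    else:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            meta_interval, meta_pixel = _calibration_from_tiff(tif)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {frames.shape}")
    if frames.shape[0] < 2:
        raise ValueError("need >= 2 frames")

    def resolve(explicit, meta, name):
        if explicit is not None:
            if meta is not None and not np.isclose(explicit, meta, rtol=1e-3):
                logger.warning(
                    "%s: explicit %s=%g overrides metadata value %g",
                    path, name, explicit, meta,
                )
            return float(explicit)
        if meta is not None:
            return float(meta)
        raise ValueError(f"{name} not in metadata and not supplied for {path}")

    return MovieStack(
        frames=frames,
        frame_interval=resolve(frame_interval, meta_interval, "frame_interval"),
        pixel_size=resolve(pixel_size, meta_pixel, "pixel_size"),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean raster as an 8-bit TIFF (255 = true)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 0


def tracks_to_frame(tracks: list[np.ndarray]) -> pd.DataFrame:
    """Flatten per-bead (frame, x, y) arrays into a tidy track table."""
    rows = []
    for tid, trk in enumerate(tracks):
        trk = np.asarray(trk, dtype=float).reshape(-1, 3)
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": trk[:, 0].astype(int),
                    "x_px": trk[:, 1],
                    "y_px": trk[:, 2],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["track_id", "frame", "x_px", "y_px"])
    return pd.concat(rows, ignore_index=True)


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record tying every reported metric to one pipeline run."""

    pipeline: str
    inputs: list[str]
    params: dict
    seed: int | None = None
    version: str = ""
    outputs: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def record(self, name: str, path: str | Path) -> None:
        self.outputs[name] = sha256_of(path)

    def write(self, path: str | Path, overwrite: bool = False) -> Path:
        path = Path(path)
        _guard_overwrite(path, overwrite)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "pipeline": self.pipeline,
            "version": self.version,
            "inputs": [str(p) for p in self.inputs],
            "params": self.params,
            "seed": self.seed,
            "outputs": self.outputs,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
        return path


def _guard_overwrite(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True (--overwrite)")


def write_outputs(
    outdir: str | Path,
    *,
    metrics: pd.DataFrame | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
    masks: dict[str, np.ndarray] | None = None,
    manifest: RunManifest | None = None,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write pipeline outputs into ``outdir`` and return name -> path.

    ``metrics`` is the tidy one-row-per-metric table
    (movie_id, group, pipeline, metric, value); ``tables`` and ``masks``
    are written as CSV and 8-bit TIFF respectively.  Existing files are
    refused unless ``overwrite`` is set; checksums of everything written
    are recorded in the manifest (written last, as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in (tables or {}).items():
        p = outdir / f"{name}.csv"
        _guard_overwrite(p, overwrite)
        df.to_csv(p, index=False, float_format="%.6g")
        written[name] = p
    for name, mask in (masks or {}).items():
        p = outdir / f"{name}.tif"
        _guard_overwrite(p, overwrite)
        write_mask(mask, p)
        written[name] = p
    if metrics is not None:
        p = outdir / "metrics.csv"
        _guard_overwrite(p, overwrite)
        metrics.to_csv(p, index=False, float_format="%.6g")
        written["metrics"] = p
    if manifest is not None:
        for name, p in written.items():
            manifest.record(name, p)
        written["manifest"] = manifest.write(outdir / "manifest.json", overwrite)
    return written
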