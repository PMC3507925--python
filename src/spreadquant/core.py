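"""Shared domain types and image/table I/O.

Conventions used throughout the package:

* Coordinates are 0-based ``(row, column)`` with row 0 at the image top.
* Binary masks are plain 2-D boolean :class:`numpy.ndarray` objects.
* Label images carry non-negative integer labels with 0 meaning background.
* Frame ``k`` of a movie is at ``t = k * frame_interval`` minutes; ``t = 0``
  is the first captured frame.
* Intensities are handled as real numbers internally regardless of the dtype
  a file stores them in.
* Areas are pixel counts; if a pixel size is known, micrometre² values are
  ``area_px * pixel_size**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Movie",
    "LabelImage",
    "RunConfig",
    "FormatError",
    "read_movie",
    "write_movie",
    "write_table",
    "read_table",
    "FRAME_TABLE_COLUMNS",
    "TRACK_TABLE_COLUMNS",
]

#: Column schema of the tidy per-frame measurement table (one row per cell
#: per frame).
FRAME_TABLE_COLUMNS = (
    "track_id",
    "frame",
    "t_min",
    "area_px",
    "protrusion_px",
    "retraction_px",
    "circle_ratio",
    "sigma_n",
)

#: Column schema of the per-track scalar table.
TRACK_TABLE_COLUMNS = ("track_id", "m", "delta_sigma_n", "n_frames", "validated")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass(frozen=True)
class Movie:
    """An ordered single-channel fluorescence image stack.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``; intensities in
        arbitrary units.
    frame_interval
        Minutes between consecutive frames; must be positive.
    pixel_size
        Micrometres per pixel (isotropic). Defaults to 1.0, in which case
        areas are effectively reported in pixels.
    channel_name
        Free-text channel description (e.g. ``"GFP-Lifeact"``).
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float = 1.0
    channel_name: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, height, width) stack with >= 1 frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Height × width of every frame."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in minutes (t=0 at first frame)."""
        return np.arange(self.n_frames) * float(self.frame_interval)


@dataclass(frozen=True)
class LabelImage:
    """Per-frame segmentation result: integer labels, 0 = background."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("label grid must be 2-D")
        if grid.size and grid.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "grid", grid.astype(np.int32, copy=False))

    @property
    def label_ids(self) -> frozenset[int]:
        """Set of positive labels present in the grid."""
        ids = np.unique(self.grid)
        return frozenset(int(i) for i in ids if i > 0)

    def mask_of(self, label: int) -> np.ndarray:
        """Boolean mask of one labelled object."""
        m = self.grid == label
        if not m.any():
            raise KeyError(f"label {label} not present")
        return m

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class RunConfig:
    """Every knob a pipeline run consumes, with reproducible defaults.

    ``fa_exclusion_regions`` are ``(row, col, radius)`` discs, in pixels,
    inside which focal-adhesion detections are discarded (nuclear-spot
    exclusion).
    """

    smoothing_sigma: float = 2.0
    h_frac: float = 0.05
    min_object_area: int = 100
    background_similarity_tol: float = 0.2
    max_gap_frames: int = 5
    rate_window_minutes: float = 30.0
    frame_interval: float = 5.0
    pixel_size: float = 1.0
    fixed_cell_threshold: float | None = None
    fa_outline_threshold: float | None = None
    fa_threshold: float | None = None
    fa_min_area: int = 4
    fa_max_area: int = 400
    fa_enhance_sigma: float = 10.0
    fa_exclusion_regions: list[tuple[float, float, float]] = field(default_factory=list)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if self.rate_window_minutes <= 0:
            raise ValueError("rate_window_minutes must be positive")
        if self.background_similarity_tol <= 0:
            raise ValueError("background_similarity_tol must be positive")


def read_movie(path: str | Path, frame_interval: float, pixel_size: float = 1.0,
               channel_name: str = "") -> Movie:
    """Read a single- or multi-page TIFF/OME-TIFF as a :class:`Movie`.

    Pages are ordered by page index. Integer intensities are preserved
    losslessly (converted to float for internal processing).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise FormatError(f"{path}: pages have mixed shapes {sorted(shapes)}")
            stack = tif.asarray()
    except (OSError, tifffile.TiffFileError) as exc:  # unreadable / not a TIFF
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3:
        raise FormatError(
            f"{path}: expected a stack of identically shaped 2-D pages, got shape {stack.shape}"
        )
    return Movie(frames=stack.astype(float), frame_interval=frame_interval,
                 pixel_size=pixel_size, channel_name=channel_name)


def write_movie(movie: Movie, path: str | Path, dtype: np.dtype | str = "uint16") -> None:
    """Write a movie as a multi-page TIFF, rounding to the target dtype."""
    frames = movie.frames
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        frames = np.clip(np.rint(frames), info.min, info.max)
    tifffile.imwrite(Path(path), frames.astype(dtype))


def write_labels(labels: Sequence[LabelImage], path: str | Path) -> None:
    """Write a sequence of label images as a 16-bit multi-page TIFF."""
    stack = np.stack([l.grid for l in labels]).astype(np.uint16)
    tifffile.imwrite(Path(path), stack)


def read_labels(path: str | Path) -> list[LabelImage]:
    stack = tifffile.imread(Path(path))
    if stack.ndim == 2:
        stack = stack[None, ...]
    return [LabelImage(frame.astype(np.int32)) for frame in stack]


def write_table(records: Sequence[Mapping[str, object]] | pd.DataFrame,
                path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write measurement records to CSV with full floating-point precision.

    All records must share one column schema; a heterogeneous sequence raises
    ``ValueError``. An empty sequence yields a header-only file (``columns``
    must then be given).
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            schema = tuple(records[0].keys())
            for r in records[1:]:
                if tuple(r.keys()) != schema:
                    raise ValueError("records have heterogeneous schemas")
            df = pd.DataFrame.from_records(records, columns=list(schema))
        else:
            if columns is None:
                raise ValueError("columns required to write an empty table")
            df = pd.DataFrame(columns=list(columns))
    if columns is not None:
        df = df.reindex(columns=list(columns))
    # repr round-trips float64 exactly
    df.to_csv(path, index=False, float_format=None)


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so written float64 values read back bit-identical
    return pd.read_csv(Path(path), float_precision="round_trip")
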