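"""Kinetic and shape read-outs of spreading cells.

Per tracked cell this module computes

* the spread-area trace (pixel count per frame) and the initial spreading
  rate ``m`` — the least-squares slope of area against time over the first
  part of the movie, reported per hour;
* protrusion/retraction between consecutive frames by mask differencing:
  pixels gained are protrusion, pixels lost are retraction, both also
  expressed as fractions of the cell area in the second frame;
* the circle ratio — cell area divided by the area of the circle whose
  radius is the distance from the cell centre to the most distant boundary
  pixel (1 for a perfect disk, smaller for angular cells);
* σ_n — the standard deviation of the centre-to-boundary distances divided
  by their mean, a scale-free irregularity measure;
* Δσ_n — the mean absolute frame-to-frame change of σ_n, a shape-remodelling
  rate.

The cell centre is the area centroid of the binary mask. Boundary pixels
are mask pixels with at least one non-mask 4-neighbour (image borders count
as non-mask); distances are measured between pixel centres. σ_n uses the
population standard deviation, the boundary being the full contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import CellTrack

__all__ = [
    "AreaTrace",
    "FrameDelta",
    "ShapeSeries",
    "area_trace",
    "standardize_areas",
    "spreading_rate",
    "protrusion_retraction",
    "boundary_pixels",
    "circle_ratio",
    "radial_sigma_n",
    "delta_sigma_n",
    "field_mean_area",
]


@dataclass(frozen=True)
class AreaTrace:
    """Spread area against time for one track (gap frames omitted)."""

    track_id: int
    times: np.ndarray  # minutes
    areas: np.ndarray  # px (or dimensionless once standardized)
    frames: np.ndarray  # original frame indices

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        f = np.asarray(self.frames, dtype=int)
        if t.ndim != 1 or t.shape != a.shape or t.shape != f.shape:
            raise ValueError("times, areas and frames must be 1-D and equal length")
        if t.size == 0:
            raise ValueError("empty trace")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("areas must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "frames", f)


@dataclass(frozen=True)
class FrameDelta:
    """Protrusion/retraction between one pair of consecutive masks."""

    frame_pair: tuple[int, int]
    protrusion_px: int
    retraction_px: int
    protrusion_frac: float  # fraction of the area in the second frame
    retraction_frac: float


@dataclass(frozen=True)
class ShapeSeries:
    """Per-frame circle ratio and σ_n for a track, plus the Δσ_n scalar."""

    track_id: int
    frames: np.ndarray
    circle_ratios: np.ndarray
    sigma_n: np.ndarray
    delta_sigma_n: float


def area_trace(track: CellTrack, frame_interval: float) -> AreaTrace:
    """Pixel-count area at every present frame; t = frame × interval."""
    if track.n_frames == 0:
        raise ValueError("track has no regions")
    frames = np.array(track.frames)
    areas = np.array([track.area(f) for f in frames], dtype=float)
    return AreaTrace(track_id=track.track_id, times=frames * float(frame_interval),
                     areas=areas, frames=frames)


def standardize_areas(traces: list[AreaTrace], control: list[AreaTrace]) -> list[AreaTrace]:
    """Divide every area by the mean first-frame area of a control group.

    The control group's own first-frame mean maps to exactly 1.0, so
    standardized areas are dimensionless fold-changes over the control
    starting area.
    """
    if not control:
        raise ValueError("control group is empty")
    reference = float(np.mean([tr.areas[0] for tr in control]))
    if reference == 0:
        raise ValueError("zero reference area")
    return [AreaTrace(track_id=tr.track_id, times=tr.times,
                      areas=tr.areas / reference, frames=tr.frames)
            for tr in traces]


def spreading_rate(trace: AreaTrace, window: float = 30.0) -> float | None:
    """Initial spreading rate ``m``: area gained per hour early in the movie.

    Least-squares slope of area vs time over the points with ``t <= window``
    minutes (window inclusive; default 30), converted to per-hour units.
    Returns None when fewer than two points fall in the window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    sel = trace.times <= window
    if sel.sum() < 2:
        return None
    t = trace.times[sel]
    a = trace.areas[sel]
    slope_per_min = np.polyfit(t, a, 1)[0]
    return float(slope_per_min * 60.0)


def protrusion_retraction(mask_t: np.ndarray, mask_t1: np.ndarray,
                          frame_pair: tuple[int, int] = (0, 1)) -> FrameDelta:
    """Pixels gained (protrusion) and lost (retraction) between two masks.

    Differencing the binarised frames gives +1 on gained pixels and −1 on
    lost ones; fractions divide by the cell area in the second frame. The
    conservation identity ``area(t+1) = area(t) + P − R`` holds exactly.
    """
    mask_t = np.asarray(mask_t, dtype=bool)
    mask_t1 = np.asarray(mask_t1, dtype=bool)
    if mask_t.shape != mask_t1.shape:
        raise ValueError("mask shapes differ")
    protrusion = int((mask_t1 & ~mask_t).sum())
    retraction = int((mask_t & ~mask_t1).sum())
    area_t1 = int(mask_t1.sum())
    if area_t1 == 0:
        p_frac = r_frac = float("nan")
    else:
        p_frac = protrusion / area_t1
        r_frac = retraction / area_t1
    return FrameDelta(frame_pair=frame_pair, protrusion_px=protrusion,
                      retraction_px=retraction, protrusion_frac=p_frac,
                      retraction_frac=r_frac)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of mask pixels with a non-mask 4-neighbour."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(mask & ~interior)


def _radial_distances(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    centre = np.argwhere(mask).mean(axis=0)
    bpix = boundary_pixels(mask)
    return np.hypot(bpix[:, 0] - centre[0], bpix[:, 1] - centre[1])


def circle_ratio(mask: np.ndarray) -> float:
    """Cell area over the area of its centre-to-farthest-edge circle.

    The circle's radius is the maximum distance from the area centroid to a
    boundary pixel centre; a single-pixel mask returns 1.0 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    if area == 1:
        return 1.0
    r_max = float(_radial_distances(mask).max())
    if r_max == 0:
        return 1.0
    return area / (np.pi * r_max ** 2)


def radial_sigma_n(mask: np.ndarray) -> float:
    """Normalised radial spread σ_n = sd(d_i)/mean(d_i) over boundary pixels.

    Dividing by the mean distance corrects for cell size, so σ_n is
    scale-free: 0 for a radially constant outline, larger for lobed ones.
    """
    d = _radial_distances(np.asarray(mask, dtype=bool))
    if d.size < 2:
        raise ValueError("mask has fewer than 2 boundary pixels")
    mean = float(d.mean())
    if mean == 0:
        raise ValueError("degenerate mask")
    return float(d.std(ddof=0) / mean)


def delta_sigma_n(sigma_series: np.ndarray) -> float:
    """Mean absolute change of σ_n between consecutive measured frames."""
    s = np.asarray(sigma_series, dtype=float)
    s = s[~np.isnan(s)]
    if s.size < 2:
        raise ValueError("need >= 2 sigma_n values")
    return float(np.mean(np.abs(np.diff(s))))


def shape_series(track: CellTrack) -> ShapeSeries:
    """Circle ratio and σ_n per present frame, with the per-track Δσ_n.

    Δσ_n pairs only consecutive present frames; frames separated by a
    detection gap contribute no pair.
    """
    frames = np.array(track.frames)
    cr = np.array([circle_ratio(track.regions[f]) for f in frames])
    sn = np.array([radial_sigma_n(track.regions[f]) for f in frames])
    diffs = [abs(sn[i + 1] - sn[i]) for i in range(len(frames) - 1)
             if frames[i + 1] == frames[i] + 1]
    dsn = float(np.mean(diffs)) if diffs else float("nan")
    return ShapeSeries(track_id=track.track_id, frames=frames,
                       circle_ratios=cr, sigma_n=sn, delta_sigma_n=dsn)


def field_mean_area(traces: list[AreaTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean spread area over all tracked objects in a field.

    At each frame the mean is taken over the traces with a defined area
    there (tracks in gap or out of range contribute nothing). Returns
    ``(frames, mean_areas)``.
    """
    if not traces:
        raise ValueError("no traces")
    all_frames = sorted({int(f) for tr in traces for f in tr.frames})
    means = []
    for f in all_frames:
        vals = [tr.areas[list(tr.frames).index(f)] for tr in traces if f in tr.frames]
        means.append(float(np.mean(vals)))
    return np.array(all_frames), np.array(means)
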