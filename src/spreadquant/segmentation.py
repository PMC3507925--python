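"""Cell detection by smoothing + local watershed, and fixed-cell areas.

Live-cell frames are segmented by Gaussian smoothing followed by a seeded
watershed: seeds are the smoothed image's intensity peaks that survive
h-maxima suppression (local maxima shallower than a depth ``h`` are merged
into their neighbours), and the watershed floods the inverted smoothed image
within an Otsu foreground mask, giving one object per intensity peak region.
Background structures that slip through are removed afterwards by comparing
each object's mean intensity with the whole-image mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import relabel_sequential, watershed

from .core import LabelImage

__all__ = [
    "SegmentationParams",
    "segment_cells",
    "filter_background_objects",
    "measure_fixed_cell_areas",
]

# objects use 8-connectivity throughout
_STRUCT8 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the smoothing + local-watershed detector.

    smoothing_sigma
        Gaussian smoothing in pixels applied before seeding and flooding.
    h_frac
        Seed suppression depth as a fraction of the smoothed frame's dynamic
        range; peaks shallower than this are not separate objects.
    min_object_area
        Pixel floor below which detected objects are discarded (debris).
    background_similarity_tol
        Multiplicative margin of :func:`filter_background_objects`.
    """

    smoothing_sigma: float = 2.0
    h_frac: float = 0.05
    min_object_area: int = 100
    background_similarity_tol: float = 0.2

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")
        if self.background_similarity_tol <= 0:
            raise ValueError("background_similarity_tol must be positive")


def _remove_small(grid: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 1:
        return grid
    ids, counts = np.unique(grid, return_counts=True)
    small = ids[(ids > 0) & (counts < min_area)]
    if small.size:
        grid[np.isin(grid, small)] = 0
    return grid


def segment_cells(frame: np.ndarray, params: SegmentationParams | None = None) -> LabelImage:
    """Detect cells in one intensity frame.

    Returns disjoint labelled objects; a structureless (near-uniform) frame
    yields an empty labelling. Labels are renumbered 1..n in scan order.
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame is empty")

    smooth = gaussian(frame, sigma=params.smoothing_sigma, preserve_range=True)
    rng_span = float(smooth.max() - smooth.min())
    if rng_span <= 0 or not np.isfinite(rng_span):
        return LabelImage(np.zeros(frame.shape, dtype=np.int32))

    # seeds come from a coarser smoothing scale than the flooding surface,
    # so residual noise peaks inside one cell do not split it
    seed_img = gaussian(smooth, sigma=params.smoothing_sigma, preserve_range=True)
    h = params.h_frac * float(np.ptp(seed_img))
    seeds = h_maxima(seed_img, h)
    markers, n_seeds = ndi.label(seeds, structure=_STRUCT8)
    if n_seeds == 0:
        return LabelImage(np.zeros(frame.shape, dtype=np.int32))

    foreground = smooth >= threshold_otsu(smooth)
    grid = watershed(-smooth, markers=markers, mask=foreground, connectivity=2)
    grid = _remove_small(grid.astype(np.int32), params.min_object_area)
    grid, _, _ = relabel_sequential(grid)
    return LabelImage(grid.astype(np.int32))


def filter_background_objects(labels: LabelImage, frame: np.ndarray,
                              tol: float = 0.2) -> LabelImage:
    """Discard objects whose mean intensity is similar to the whole-image mean.

    An object is retained iff ``mean(frame over object) >= (1 + tol) *
    mean(frame over all pixels)``; everything else is background structure
    erroneously picked up by the watershed. The whole-image mean includes the
    object's own pixels.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != labels.shape:
        raise ValueError("labels and frame shapes differ")
    grid = labels.grid.copy()
    image_mean = float(frame.mean())
    for lab in sorted(labels.label_ids):
        obj_mean = float(frame[grid == lab].mean())
        if obj_mean < (1.0 + tol) * image_mean:
            grid[grid == lab] = 0
    return LabelImage(grid)


def measure_fixed_cell_areas(image: np.ndarray, threshold: float | None = None,
                             min_object_area: int = 100) -> list[tuple[int, int]]:
    """Spread areas of fixed, stained cells by thresholding.

    Connected components (8-connectivity) of ``image > threshold`` with at
    least ``min_object_area`` pixels are reported as ``(cell_id, area_px)``
    pairs. When ``threshold`` is None, Otsu's method picks it.
    """
    image = np.asarray(image, dtype=float)
    if threshold is None:
        if image.max() == image.min():
            return []
        threshold = float(threshold_otsu(image))
    binary = image > threshold
    if not binary.any():
        return []
    grid = cc_label(binary, connectivity=2)
    out: list[tuple[int, int]] = []
    cell_id = 0
    for lab in range(1, grid.max() + 1):
        area = int((grid == lab).sum())
        if area >= min_object_area:
            cell_id += 1
            out.append((cell_id, area))
    return out
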