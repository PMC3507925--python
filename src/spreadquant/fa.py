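"""Focal-adhesion composition in fixed, immunostained cells.

The measurement chain per cell:

1. the cell outline is found by thresholding the actin (phalloidin)
   counterstain — or the paxillin channel itself in dual stains;
2. focal adhesions (FAs) are detected on the paxillin or vinculin signal by
   top-hat-style enhancement followed by a local watershed on the puncta,
   keeping only objects fully inside the cell and outside user-specified
   exclusion discs (which remove falsely detected nuclear spots);
3. the mean intensity outside the cell (camera and other noise) is
   subtracted from the whole image;
4. the mean corrected intensity inside the cell but outside FAs is the
   cellular background;
5. the total corrected FA intensity, divided by the cellular background,
   is the normalised FA level — dimensionless and robust to exposure, so
   comparable across cells imaged under the same conditions;
6. in dual stains the paxillin-derived FA mask is reused to read the
   phospho-channel, and the ratio of the two normalised levels is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import relabel_sequential, watershed

import pandas as pd

from .core import LabelImage

__all__ = [
    "FAScene",
    "FAMeasurement",
    "detect_cell_outline",
    "detect_fas",
    "camera_background",
    "subtract_camera_background",
    "cellular_background",
    "normalized_fa_intensity",
    "measure_scene",
    "dual_stain_measure",
    "standardize_condition",
]

_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class FAScene:
    """One fixed-cell field: FA channel(s) plus an outline channel.

    ``exclusion_regions`` are ``(row, col, radius)`` discs in pixels; FA
    detections intersecting any of them are discarded (nuclear spots).
    """

    primary_channel: np.ndarray
    outline_channel: np.ndarray | None = None
    secondary_channel: np.ndarray | None = None
    exclusion_regions: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.primary_channel = np.asarray(self.primary_channel, dtype=float)
        for name in ("outline_channel", "secondary_channel"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.shape != self.primary_channel.shape:
                    raise ValueError(f"{name} shape differs from primary channel")
                setattr(self, name, ch)


@dataclass(frozen=True)
class FAMeasurement:
    """Background-corrected FA read-outs for one cell."""

    cell_id: int
    n_fas: int
    camera_bg: float
    cellular_bg: float
    normalized_total_intensity: float
    secondary_camera_bg: float | None = None
    secondary_cellular_bg: float | None = None
    secondary_normalized_intensity: float | None = None
    ratio: float | None = None  # secondary / primary, dual-stain mode


def detect_cell_outline(outline_channel: np.ndarray,
                        threshold: float | None = None) -> np.ndarray:
    """Cell mask by thresholding the counterstain: largest component, holes filled."""
    img = np.asarray(outline_channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty channel")
    if threshold is None:
        if img.max() == img.min():
            raise ValueError("nothing above threshold (uniform image)")
        threshold = float(threshold_otsu(img))
    binary = img > threshold
    if not binary.any():
        raise ValueError("nothing above threshold")
    lab = cc_label(binary, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return ndi.binary_fill_holes(lab == largest)


def _exclusion_mask(shape: tuple[int, int],
                    regions: list[tuple[float, float, float]]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if not regions:
        return mask
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    for r0, c0, radius in regions:
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    return mask


def detect_fas(primary_channel: np.ndarray, cell_mask: np.ndarray,
               exclusion_regions: list[tuple[float, float, float]] | None = None,
               threshold: float | None = None,
               enhance_sigma: float = 10.0,
               min_area: int = 4, max_area: int = 400) -> LabelImage:
    """Detect FA puncta inside the cell by enhancement + local watershed.

    A smoothed (``enhance_sigma``-scale) copy of the image is subtracted to
    flatten the diffuse cytoplasmic signal before seeding the watershed, so
    only small bright puncta survive. Objects outside ``[min_area,
    max_area]`` pixels, touching the cell edge/exterior, or intersecting an
    exclusion disc are discarded.
    """
    img = np.asarray(primary_channel, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if img.shape != cell_mask.shape:
        raise ValueError("channel and cell mask shapes differ")
    empty = LabelImage(np.zeros(img.shape, dtype=np.int32))

    enhanced = img - gaussian(img, sigma=enhance_sigma, preserve_range=True)
    enhanced = np.clip(enhanced, 0, None)
    inside = enhanced[cell_mask]
    if inside.size == 0 or inside.max() <= 0:
        return empty
    if threshold is None:
        if np.ptp(inside) == 0:
            return empty
        threshold = float(threshold_otsu(inside))
    fg = (enhanced > threshold) & cell_mask
    if not fg.any():
        return empty

    smooth = gaussian(enhanced, sigma=1.0, preserve_range=True)
    h = 0.05 * float(np.ptp(smooth))
    seeds, n_seeds = ndi.label(h_maxima(smooth, h) & fg, structure=_STRUCT8)
    if n_seeds == 0:
        seeds, n_seeds = ndi.label(fg, structure=_STRUCT8)
    grid = watershed(-smooth, markers=seeds, mask=fg, connectivity=2).astype(np.int32)

    excl = _exclusion_mask(img.shape, exclusion_regions or [])
    outside = ~cell_mask
    for lab in range(1, grid.max() + 1):
        obj = grid == lab
        area = int(obj.sum())
        # "strictly inside": an object touching the cell edge (i.e. whose
        # 1-px dilation reaches outside the cell) is a straddling punctum
        touches_edge = bool((ndi.binary_dilation(obj, _STRUCT8) & outside).any())
        bad = (area < min_area or area > max_area
               or touches_edge
               or bool((obj & excl).any()))
        if bad:
            grid[obj] = 0
    grid, _, _ = relabel_sequential(grid)
    return LabelImage(grid.astype(np.int32))


def camera_background(image: np.ndarray, cell_mask: np.ndarray,
                      min_outside_px: int = 100) -> float:
    """Mean intensity outside the cell: the camera/noise floor to subtract."""
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if image.shape != cell_mask.shape:
        raise ValueError("shapes differ")
    outside = image[~cell_mask]
    if outside.size < min_outside_px:
        raise ValueError(f"only {outside.size} pixels outside the cell (need {min_outside_px})")
    return float(outside.mean())


def subtract_camera_background(image: np.ndarray, camera_bg: float) -> np.ndarray:
    """Camera-noise subtraction, clamped at zero (negative pixels → 0)."""
    return np.clip(np.asarray(image, dtype=float) - camera_bg, 0.0, None)


def cellular_background(corrected_image: np.ndarray, cell_mask: np.ndarray,
                        fa_labels: LabelImage | None = None) -> float:
    """Mean corrected intensity inside the cell, excluding FA pixels."""
    corrected_image = np.asarray(corrected_image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    region = cell_mask.copy()
    if fa_labels is not None:
        region &= fa_labels.grid == 0
    if not region.any():
        raise ValueError("cell interior minus FA pixels is empty")
    return float(corrected_image[region].mean())


def normalized_fa_intensity(corrected_image: np.ndarray, fa_labels: LabelImage,
                            cellular_bg: float) -> float:
    """Total corrected FA intensity divided by the cellular background."""
    if cellular_bg <= 0:
        raise ValueError("cellular background must be positive")
    fa_px = fa_labels.grid > 0
    total = float(np.asarray(corrected_image, dtype=float)[fa_px].sum())
    return total / cellular_bg


def _channel_measure(channel: np.ndarray, cell_mask: np.ndarray,
                     fa_labels: LabelImage) -> tuple[float, float, float]:
    cam = camera_background(channel, cell_mask)
    corrected = subtract_camera_background(channel, cam)
    cell_bg = cellular_background(corrected, cell_mask, fa_labels)
    norm = normalized_fa_intensity(corrected, fa_labels, cell_bg)
    return cam, cell_bg, norm


def measure_scene(scene: FAScene, cell_id: int = 1,
                  outline_threshold: float | None = None,
                  fa_threshold: float | None = None,
                  enhance_sigma: float = 10.0,
                  min_area: int = 4, max_area: int = 400,
                  fa_labels: LabelImage | None = None,
                  cell_mask: np.ndarray | None = None) -> FAMeasurement:
    """Full single- or dual-stain measurement of one scene.

    The FA mask always comes from the primary (paxillin/vinculin) channel;
    in dual-stain mode the secondary channel is corrected and normalised
    with its own camera and cellular backgrounds on the same pixel set, and
    ``ratio = normalised secondary / normalised primary``. Precomputed
    ``cell_mask``/``fa_labels`` may be supplied (e.g. ground truth).
    """
    if cell_mask is None:
        outline = scene.outline_channel if scene.outline_channel is not None \
            else scene.primary_channel
        cell_mask = detect_cell_outline(outline, outline_threshold)
    if fa_labels is None:
        fa_labels = detect_fas(scene.primary_channel, cell_mask,
                               scene.exclusion_regions, threshold=fa_threshold,
                               enhance_sigma=enhance_sigma,
                               min_area=min_area, max_area=max_area)
    cam, cell_bg, norm = _channel_measure(scene.primary_channel, cell_mask, fa_labels)
    meas = dict(cell_id=cell_id, n_fas=len(fa_labels.label_ids),
                camera_bg=cam, cellular_bg=cell_bg,
                normalized_total_intensity=norm)
    if scene.secondary_channel is not None:
        cam2, bg2, norm2 = _channel_measure(scene.secondary_channel, cell_mask, fa_labels)
        meas.update(secondary_camera_bg=cam2, secondary_cellular_bg=bg2,
                    secondary_normalized_intensity=norm2,
                    ratio=(norm2 / norm) if norm > 0 else (0.0 if norm2 == 0 else float("inf")))
    return FAMeasurement(**meas)


def dual_stain_measure(scene: FAScene, **kwargs) -> FAMeasurement:
    """Dual-stain convenience wrapper around :func:`measure_scene`."""
    return measure_scene(scene, **kwargs)


def standardize_condition(values: pd.DataFrame, reference_condition: str,
                          value_col: str = "normalized_total_intensity",
                          condition_col: str = "condition") -> pd.DataFrame:
    """Standardise pooled per-cell values to a reference condition's mean.

    Every value is divided by the grand mean of the reference condition over
    all experiments pooled, so the reference condition's mean maps to
    exactly 1.0 and conditions are comparable across experiments.
    """
    if reference_condition not in set(values[condition_col]):
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref_mean = float(values.loc[values[condition_col] == reference_condition, value_col].mean())
    if ref_mean == 0:
        raise ValueError("reference condition has zero mean")
    out = values.copy()
    out[value_col + "_standardized"] = out[value_col] / ref_mean
    return out
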