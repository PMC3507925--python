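"""Overlap-based cell tracking with gap bridging.

Objects are linked between consecutive frames by maximal pixel overlap (at
least one shared pixel required, one-to-one). When a cell's detection is
lost, its last seen mask is tested against each of the following frames and
the track resumes at the first overlapping object; a track whose detection
stays lost for more than ``max_gap`` consecutive frames is closed. Cells are
assumed not to divide or fuse over the few hours of a spreading movie, so
merges and splits are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import LabelImage, Movie

__all__ = [
    "CellTrack",
    "link_frames",
    "build_tracks",
    "crop_to_single_cell",
    "flag_validation",
]


@dataclass
class CellTrack:
    """One cell's linked per-frame masks across a movie.

    ``regions`` maps frame index → boolean mask; frames strictly inside
    ``[start_frame, end_frame]`` that are missing from the map are detection
    gaps (they contribute no measurements downstream).
    """

    track_id: int
    regions: dict[int, np.ndarray] = field(default_factory=dict)
    validated: bool = False

    @property
    def start_frame(self) -> int:
        return min(self.regions)

    @property
    def end_frame(self) -> int:
        return max(self.regions)

    @property
    def frames(self) -> list[int]:
        """Present (non-gap) frame indices, sorted."""
        return sorted(self.regions)

    @property
    def n_frames(self) -> int:
        return len(self.regions)

    def area(self, frame: int) -> int:
        return int(self.regions[frame].sum())


def _pair_overlaps(grid_a: np.ndarray, grid_b: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel overlap count for every co-occurring (label_a, label_b) pair."""
    both = (grid_a > 0) & (grid_b > 0)
    if not both.any():
        return {}
    pairs = np.stack([grid_a[both], grid_b[both]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(uniq.T, counts)}


def link_frames(labels_t: LabelImage, labels_t1: LabelImage) -> list[tuple[int, int, int]]:
    """Match objects between consecutive frames by maximal pixel overlap.

    Returns ``(label_t, label_t1, overlap_px)`` triples; each object appears
    in at most one triple. Ties on overlap go to the candidate with larger
    area, then to the lower label id. Objects without a triple are track
    ends (in ``labels_t``) or births (in ``labels_t1``).
    """
    if labels_t.shape != labels_t1.shape:
        raise ValueError("label images have different shapes")
    overlaps = _pair_overlaps(labels_t.grid, labels_t1.grid)
    if not overlaps:
        return []
    areas_t1 = {lab: int((labels_t1.grid == lab).sum()) for lab in labels_t1.label_ids}
    ordered = sorted(overlaps.items(),
                     key=lambda kv: (-kv[1], -areas_t1[kv[0][1]], kv[0][0], kv[0][1]))
    used_t: set[int] = set()
    used_t1: set[int] = set()
    matches: list[tuple[int, int, int]] = []
    for (a, b), ov in ordered:
        if a in used_t or b in used_t1:
            continue
        used_t.add(a)
        used_t1.add(b)
        matches.append((a, b, ov))
    return matches


def build_tracks(labels: Sequence[LabelImage], max_gap: int = 5) -> list[CellTrack]:
    """Link a sequence of label images into tracks, bridging detection gaps.

    Greedy frame-by-frame linking; a vanished object's last mask is compared
    against each of the next frames and the track resumes at the first
    overlapping (still unclaimed) object, provided the gap does not exceed
    ``max_gap`` absent frames. Track ids are assigned in order of first
    appearance.
    """
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    tracks: list[CellTrack] = []
    # active track bookkeeping: track -> (last_frame, last_label, last_mask)
    active: dict[int, tuple[int, int, np.ndarray]] = {}

    def open_track(frame: int, lab: int, mask: np.ndarray) -> None:
        t = CellTrack(track_id=len(tracks) + 1, regions={frame: mask})
        tracks.append(t)
        active[t.track_id] = (frame, lab, mask)

    first = labels[0]
    for lab in sorted(first.label_ids):
        open_track(0, lab, first.grid == lab)

    for i in range(1, len(labels)):
        cur = labels[i]
        claimed: set[int] = set()

        # 1. consecutive-frame matches take precedence
        consecutive = {tid: info for tid, info in active.items() if info[0] == i - 1}
        if consecutive:
            matches = {a: (b, ov) for a, b, ov in link_frames(labels[i - 1], cur)}
            for tid, (f, lab, _mask) in sorted(consecutive.items()):
                if lab in matches:
                    new_lab, _ = matches[lab]
                    new_mask = cur.grid == new_lab
                    tracks[tid - 1].regions[i] = new_mask
                    active[tid] = (i, new_lab, new_mask)
                    claimed.add(new_lab)

        # 2. gap-state tracks try to resume on still-unclaimed objects
        for tid in sorted(active):
            f, _lab, last_mask = active[tid]
            if f >= i:
                continue
            if i - f - 1 > max_gap:  # gap can no longer close
                del active[tid]
                continue
            best: tuple[int, int, int] | None = None  # (-overlap, -area, label)
            for lab in sorted(cur.label_ids - claimed):
                obj = cur.grid == lab
                ov = int((obj & last_mask).sum())
                if ov >= 1:
                    key = (-ov, -int(obj.sum()), lab)
                    if best is None or key < best:
                        best = key
            if best is not None:
                lab = best[2]
                new_mask = cur.grid == lab
                tracks[tid - 1].regions[i] = new_mask
                active[tid] = (i, lab, new_mask)
                claimed.add(lab)

        # 3. leftover objects are births
        for lab in sorted(cur.label_ids - claimed):
            open_track(i, lab, cur.grid == lab)

    return tracks


def crop_to_single_cell(movie: Movie, roi: tuple[int, int, int, int]) -> Movie:
    """Crop all frames identically to ``roi = (row, col, height, width)``.

    Supports the single-cell analysis mode where each movie is cropped so
    only one cell is visible per frame.
    """
    r, c, h, w = roi
    H, W = movie.shape
    if r < 0 or c < 0 or h < 1 or w < 1 or r + h > H or c + w > W:
        raise ValueError(f"roi {roi} outside frame bounds {H}x{W}")
    return replace(movie, frames=movie.frames[:, r:r + h, c:c + w])


def flag_validation(tracks: Sequence[CellTrack],
                    decisions: Mapping[int, bool]) -> list[CellTrack]:
    """Apply manual track-validation decisions.

    Unknown track ids raise ``KeyError``; tracks without a decision keep
    their current flag. Downstream metric tables include only validated
    tracks unless configured otherwise.
    """
    by_id = {t.track_id: t for t in tracks}
    for tid in decisions:
        if tid not in by_id:
            raise KeyError(f"unknown track_id {tid}")
    out = []
    for t in tracks:
        v = decisions.get(t.track_id, t.validated)
        out.append(CellTrack(track_id=t.track_id, regions=dict(t.regions), validated=v))
    return out
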