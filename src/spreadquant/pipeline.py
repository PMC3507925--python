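"""End-to-end analyses wiring segmentation → tracking → metrics, and FA mode."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (FRAME_TABLE_COLUMNS, TRACK_TABLE_COLUMNS, LabelImage, Movie,
                   RunConfig)
from .fa import FAScene, measure_scene
from .metrics import area_trace, protrusion_retraction, shape_series, spreading_rate
from .segmentation import SegmentationParams, filter_background_objects, segment_cells
from .tracking import CellTrack, build_tracks

__all__ = [
    "segment_movie",
    "track_movie",
    "tracks_to_tables",
    "analyze_movie",
    "analyze_fa_scene",
]


def segment_movie(movie: Movie, config: RunConfig | None = None) -> list[LabelImage]:
    """Segment every frame and discard background-like objects."""
    config = config or RunConfig()
    params = SegmentationParams(
        smoothing_sigma=config.smoothing_sigma, h_frac=config.h_frac,
        min_object_area=config.min_object_area,
        background_similarity_tol=config.background_similarity_tol)
    out = []
    for frame in movie.frames:
        labels = segment_cells(frame, params)
        labels = filter_background_objects(labels, frame,
                                           config.background_similarity_tol)
        out.append(labels)
    return out


def track_movie(labels: list[LabelImage], config: RunConfig | None = None) -> list[CellTrack]:
    config = config or RunConfig()
    return build_tracks(labels, max_gap=config.max_gap_frames)


def tracks_to_tables(tracks: list[CellTrack], frame_interval: float,
                     rate_window: float = 30.0,
                     validated_only: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-frame and per-track measurement tables.

    Frame rows carry area, protrusion/retraction relative to the previous
    present frame (NaN at track starts and directly after gaps), circle
    ratio and σ_n; track rows carry the spreading rate ``m``, Δσ_n, length
    and validation flag.
    """
    frame_rows: list[dict] = []
    track_rows: list[dict] = []
    for track in tracks:
        if validated_only and not track.validated:
            continue
        trace = area_trace(track, frame_interval)
        shapes = shape_series(track)
        m = spreading_rate(trace, window=rate_window)
        prev_frame = None
        for i, f in enumerate(track.frames):
            prot = retr = np.nan
            if prev_frame is not None and f == prev_frame + 1:
                delta = protrusion_retraction(track.regions[prev_frame],
                                              track.regions[f], (prev_frame, f))
                prot, retr = delta.protrusion_px, delta.retraction_px
            frame_rows.append(dict(
                track_id=track.track_id, frame=int(f),
                t_min=float(trace.times[i]), area_px=float(trace.areas[i]),
                protrusion_px=prot, retraction_px=retr,
                circle_ratio=float(shapes.circle_ratios[i]),
                sigma_n=float(shapes.sigma_n[i])))
            prev_frame = f
        track_rows.append(dict(
            track_id=track.track_id,
            m=np.nan if m is None else m,
            delta_sigma_n=shapes.delta_sigma_n,
            n_frames=track.n_frames, validated=track.validated))
    frame_df = pd.DataFrame(frame_rows, columns=list(FRAME_TABLE_COLUMNS))
    track_df = pd.DataFrame(track_rows, columns=list(TRACK_TABLE_COLUMNS))
    return frame_df, track_df


def analyze_movie(movie: Movie, config: RunConfig | None = None,
                  validated_only: bool = False
                  ) -> tuple[pd.DataFrame, pd.DataFrame, list[LabelImage], list[CellTrack]]:
    """Full live-cell pipeline: segment → filter → track → metrics."""
    config = config or RunConfig()
    labels = segment_movie(movie, config)
    tracks = track_movie(labels, config)
    frame_df, track_df = tracks_to_tables(
        tracks, movie.frame_interval, rate_window=config.rate_window_minutes,
        validated_only=validated_only)
    return frame_df, track_df, labels, tracks


def analyze_fa_scene(scene: FAScene, config: RunConfig | None = None,
                     cell_id: int = 1) -> pd.DataFrame:
    """Fixed-cell FA pipeline: outline → detect → correct → normalise."""
    config = config or RunConfig()
    meas = measure_scene(
        scene, cell_id=cell_id,
        outline_threshold=config.fa_outline_threshold,
        fa_threshold=config.fa_threshold,
        enhance_sigma=config.fa_enhance_sigma,
        min_area=config.fa_min_area, max_area=config.fa_max_area)
    return pd.DataFrame([vars(meas)])
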