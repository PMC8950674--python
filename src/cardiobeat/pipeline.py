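"""End-to-end orchestration: video -> well beating result.

Chains the module stages in the order the analysis runs on a real
recording: ROI detection and cell-mask segmentation on the first frame,
reference-grid placement, Lucas-Kanade tracking, distance-profile
thresholding, per-point peak analysis and well-level aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import beat_quantification as bq
from . import motion_analysis as ma
from . import well_segmentation as ws
from .config import RunConfig
from .video_io import VideoClip

logger = logging.getLogger(__name__)

__all__ = ["VideoAnalysis", "analyze_video_clip"]


@dataclass
class VideoAnalysis:
    """Everything the video pipeline produced for one well."""

    roi: ws.WellROI
    cell_mask: ws.CellMask
    tracked: list[ma.TrackedPoint]
    profiles: list[ma.DistanceProfile]
    estimates: list[bq.BeatEstimate]
    result: bq.WellBeatResult

    def heatmap(self) -> np.ndarray:
        shape = self.cell_mask.mask.shape
        return bq.render_heatmap(self.result, shape, f_range=(0.0, 5.0))


def analyze_video_clip(clip: VideoClip, config: RunConfig | None = None) -> VideoAnalysis:
    """Run the full beating analysis on an in-memory clip."""
    config = config or RunConfig()
    first = clip.gray_frames()[0]

    roi = ws.detect_well_roi(first, padding=config.roi_padding)
    mask = ws.compute_cell_mask(
        first.astype(np.uint8),
        roi,
        lut=config.lut_tuple(),
        min_area=config.min_component_area,
    )

    grid = ma.GridSpec(spacing=config.grid_spacing, margin=config.grid_margin)
    origins = ma.place_reference_grid(clip.width, clip.height, grid)
    # only track points inside the padded ROI: nothing outside the well
    # can carry cell motion
    disc = roi.disc_mask(clip.height, clip.width)
    keep = disc[
        np.clip(np.round(origins[:, 1]).astype(int), 0, clip.height - 1),
        np.clip(np.round(origins[:, 0]).astype(int), 0, clip.width - 1),
    ]
    origins = origins[keep]

    tracked = ma.track_points(
        clip, origins, window=config.lk_window, pyramid_levels=config.pyramid_levels
    )
    alive = [tp for tp in tracked if tp.status == "tracked"]
    profiles = [ma.distance_profile(tp, alpha=config.alpha) for tp in alive]
    estimates = [
        bq.estimate_beat(
            tp,
            prof,
            clip.frame_rate,
            prominence_frac=config.prominence_frac,
            f_max=config.f_max,
            min_prominence=config.min_prominence_px,
        )
        for tp, prof in zip(alive, profiles)
    ]
    roi_area = float(roi.disc_mask(clip.height, clip.width).sum())
    result = bq.aggregate_well(estimates, mask, grid, roi_area_px2=roi_area)
    return VideoAnalysis(
        roi=roi,
        cell_mask=mask,
        tracked=tracked,
        profiles=profiles,
        estimates=estimates,
        result=result,
    )
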