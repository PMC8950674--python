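"""Well ROI detection and cell-layer segmentation.

The circular well is located on the first frame with a Hough circle
transform; the detected disc, padded by 10 px, bounds all downstream
analysis.  Inside the ROI the cell layer is segmented on the HSL lightness
channel: the mean lightness selects a binarisation threshold from a
lookup table (dense multilayers appear darker than background on
phase-contrast images), and connected components smaller than a minimum
area — dead cells and floating artifacts — are removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import feature, measure, morphology, transform

from .video_io import Frame, to_lightness

logger = logging.getLogger(__name__)

__all__ = [
    "WellROI",
    "CellMask",
    "DEFAULT_LIGHTNESS_LUT",
    "detect_well_roi",
    "compute_cell_mask",
    "export_mask",
]

#: mean-lightness quartile bin -> threshold multiplier (threshold =
#: mean_lightness * multiplier).  The brighter the well, the more
#: aggressively the cut is placed below the mean.  A calibration stand-in:
#: override via config for real recordings.
DEFAULT_LIGHTNESS_LUT: tuple[tuple[float, float], ...] = (
    (0.25, 0.95),
    (0.50, 0.90),
    (0.75, 0.85),
    (1.01, 0.80),
)


@dataclass
class WellROI:
    """Circular region of interest covering the well."""

    center: tuple[float, float]  # (x, y) px
    radius: float
    padding: float = 10.0
    detected: bool = True  # False when the inscribed-circle fallback fired

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def effective_radius(self) -> float:
        return self.radius + self.padding

    def disc_mask(self, height: int, width: int) -> np.ndarray:
        """Boolean raster of the padded ROI disc, clipped to the frame."""
        yy, xx = np.mgrid[0:height, 0:width]
        cx, cy = self.center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.effective_radius**2


@dataclass
class CellMask:
    """Binary cell-layer mask with its segmentation provenance."""

    mask: np.ndarray
    mean_lightness: float
    threshold_used: float
    min_component_area: float

    @property
    def area_px2(self) -> float:
        return float(self.mask.sum())


def detect_well_roi(
    frame: Frame | np.ndarray,
    padding: float = 10.0,
    radius_range: tuple[float, float] = (0.3, 0.6),
    n_radii: int = 25,
) -> WellROI:
    """Locate the well rim as the highest-scoring Hough circle.

    ``radius_range`` is expressed as fractions of min(H, W).  When no circle
    rises above a minimal accumulator score (e.g. a blank frame) the
    inscribed circle of the frame is returned with ``detected=False`` and a
    warning is logged.
    """
    if isinstance(frame, Frame):
        px = frame.pixels
    else:
        px = np.asarray(frame)
    if px.ndim != 2:
        raise ValueError("detect_well_roi expects a single-channel frame")
    img = px.astype(float)
    if img.max() > 1.5:  # uint8-scaled input
        img = img / 255.0
    H, W = img.shape
    rmin = int(radius_range[0] * min(H, W))
    rmax = int(radius_range[1] * min(H, W))
    radii = np.unique(np.linspace(rmin, rmax, n_radii).astype(int))
    edges = feature.canny(img, sigma=2.0)
    if edges.any():
        accum = transform.hough_circle(edges, radii)
        accums, cxs, cys, rads = transform.hough_circle_peaks(
            accum, radii, total_num_peaks=1
        )
        if len(accums) and accums[0] > 0.2:
            return WellROI(
                center=(float(cxs[0]), float(cys[0])),
                radius=float(rads[0]),
                padding=padding,
            )
    logger.warning("detect_well_roi: no circle found; falling back to inscribed circle")
    return WellROI(
        center=((W - 1) / 2.0, (H - 1) / 2.0),
        radius=min(H, W) / 2.0 - padding,
        padding=padding,
        detected=False,
    )


def _threshold_from_lut(
    mean_lightness: float, lut: tuple[tuple[float, float], ...]
) -> float:
    for upper, mult in lut:
        if mean_lightness < upper:
            return mean_lightness * mult
    return mean_lightness * lut[-1][1]


def compute_cell_mask(
    frame: Frame | np.ndarray,
    roi: WellROI,
    lut: tuple[tuple[float, float], ...] = DEFAULT_LIGHTNESS_LUT,
    min_area: float | None = None,
) -> CellMask:
    """Segment the cell layer inside the ROI on the lightness channel.

    Pixels with lightness <= threshold (cells are darker) inside the ROI
    disc are candidates; 8-connected components below ``min_area`` px^2
    (default 0.05% of the ROI area) are removed as dead cells/artifacts.
    """
    light = to_lightness(frame).pixels
    H, W = light.shape
    disc = roi.disc_mask(H, W)
    if not disc.any():
        raise ValueError("ROI does not intersect the frame")
    mean_lightness = float(light[disc].mean())
    threshold = _threshold_from_lut(mean_lightness, lut)
    if min_area is None:
        min_area = 0.0005 * float(disc.sum())
    candidates = (light <= threshold) & disc
    # the cell layer is a continuous sheet: close sub-cellular speckle holes
    # so isolated bright texture pixels do not punch points out of the mask
    candidates = morphology.closing(candidates, morphology.disk(3)) & disc
    if min_area > 0:
        labels = measure.label(candidates, connectivity=2)  # 8-connectivity
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = (sizes >= min_area)[labels]
    else:
        mask = candidates
    return CellMask(
        mask=mask,
        mean_lightness=mean_lightness,
        threshold_used=float(threshold),
        min_component_area=float(min_area),
    )


def export_mask(cell_mask: CellMask, roi: WellROI, path: str | Path) -> Path:
    """Write the mask as a 0/255 PNG plus a JSON provenance sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (cell_mask.mask.astype(np.uint8) * 255))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "center": list(roi.center),
                "radius": roi.radius,
                "padding": roi.padding,
                "detected": roi.detected,
                "mean_lightness": cell_mask.mean_lightness,
                "threshold_used": cell_mask.threshold_used,
                "min_component_area": cell_mask.min_component_area,
            },
            indent=2,
        )
    )
    return path
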