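"""Per-point beat detection and well-level beating statistics.

A reference point is *beating* when its thresholded distance profile shows
at least two accepted contraction peaks (mirroring the recording rule of at
least two contractive motions).  Its frequency is (n_peaks - 1) / (t_last -
t_first): the mean inter-beat interval over the observed peak span, which
is robust to dead time before the first and after the last contraction.

The well-level *beating area* is the number of beating grid points inside
the cell mask times spacing^2 (one lattice cell per point); it is also
reported as a percentage of the mask area.  A heatmap colour-codes each
beating point's lattice cell by its frequency in beats/second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .motion_analysis import DistanceProfile, GridSpec, TrackedPoint
from .well_segmentation import CellMask

logger = logging.getLogger(__name__)

__all__ = [
    "BeatEstimate",
    "WellBeatResult",
    "detect_peaks",
    "estimate_frequency",
    "aggregate_well",
    "render_heatmap",
]

#: physiological ceiling for hiPSC-CM beat rates, Hz
DEFAULT_F_MAX = 5.0
#: default peak prominence as a fraction of the profile's dynamic range
DEFAULT_PROMINENCE_FRAC = 0.2
#: median peak-prominence gate, px, deciding beating vs residual jitter: a
#: static point's tracking noise random-walks with a large range but only
#: shallow wiggles, while genuine contraction returns to baseline each beat
MIN_PROMINENCE_PX = 0.9


@dataclass
class BeatEstimate:
    """Beat statistics of a single reference point."""

    point_id: int
    position: tuple[float, float]  # origin (x, y)
    peak_times: np.ndarray  # seconds
    frequency: float | None  # beats/s, None unless is_beating

    @property
    def n_peaks(self) -> int:
        return int(len(self.peak_times))

    @property
    def is_beating(self) -> bool:
        return self.n_peaks >= 2


@dataclass
class WellBeatResult:
    """Aggregated beating statistics of one well."""

    estimates: list[BeatEstimate]
    grid: GridSpec
    beating_area_px2: float
    beating_area_pct_of_mask: float
    beating_area_pct_of_roi: float
    mean_frequency: float | None
    n_points_total: int
    n_points_in_mask: int
    n_points_beating: int

    def to_dict(self) -> dict:
        return {
            "n_points_total": self.n_points_total,
            "n_points_in_mask": self.n_points_in_mask,
            "n_points_beating": self.n_points_beating,
            "beating_area_px2": self.beating_area_px2,
            "beating_area_pct_of_mask": self.beating_area_pct_of_mask,
            "beating_area_pct_of_roi": self.beating_area_pct_of_roi,
            "mean_frequency_bps": self.mean_frequency,
            "frequency_formula": "(n_peaks - 1) / (t_last - t_first)",
        }


def detect_peaks(
    profile: DistanceProfile,
    frame_rate: float,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    f_max: float = DEFAULT_F_MAX,
    min_prominence: float = MIN_PROMINENCE_PX,
) -> np.ndarray:
    """Contraction peak times (s) of a thresholded distance profile.

    Peaks are local maxima with prominence >= prominence_frac * (max - min
    of the profile), separated by at least frame_rate / f_max frames.  If
    the median prominence of those maxima falls below ``min_prominence``
    px the profile is classified as residual jitter rather than
    contraction and yields no peaks, as does a flat profile.
    """
    if not 0 < prominence_frac < 1:
        raise ValueError("prominence_frac must be in (0, 1)")
    if f_max <= 0 or frame_rate <= 0:
        raise ValueError("f_max and frame_rate must be positive")
    d = np.asarray(profile.d, dtype=float)
    rng = float(d.max() - d.min())
    if rng <= 0:
        return np.empty(0)
    idx, props = signal.find_peaks(
        d,
        prominence=prominence_frac * rng,
        distance=max(1, int(np.floor(frame_rate / f_max))),
    )
    if idx.size:
        # a genuine contraction returns to baseline each beat, so its peak
        # prominences match its excursion amplitude; the residual jitter of
        # a static point drifts (large range) with only shallow wiggles
        if float(np.median(props["prominences"])) < min_prominence:
            return np.empty(0)
    return idx / frame_rate


def estimate_frequency(peak_times: np.ndarray) -> float | None:
    """Beats per second from peak times: (n - 1) / span of the peaks.

    Returns None for fewer than two peaks (frequency undefined).
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        return None
    span = float(peak_times[-1] - peak_times[0])
    if span <= 0:
        return None
    return (peak_times.size - 1) / span


def estimate_beat(
    point: TrackedPoint,
    profile: DistanceProfile,
    frame_rate: float,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    f_max: float = DEFAULT_F_MAX,
    min_prominence: float = MIN_PROMINENCE_PX,
) -> BeatEstimate:
    """Peak analysis + frequency estimate for one tracked point."""
    times = detect_peaks(profile, frame_rate, prominence_frac, f_max, min_prominence)
    freq = estimate_frequency(times)
    return BeatEstimate(
        point_id=point.point_id,
        position=point.origin,
        peak_times=times,
        frequency=freq,
    )


def aggregate_well(
    estimates: list[BeatEstimate],
    mask: CellMask,
    grid: GridSpec,
    roi_area_px2: float | None = None,
) -> WellBeatResult:
    """Combine per-point estimates into the well-level result.

    Points outside the cell mask are discarded (the mask upper-bounds the
    analysis).  Beating area = n_beating * spacing^2.
    """
    H, W = mask.mask.shape
    in_mask: list[BeatEstimate] = []
    for est in estimates:
        x, y = est.position
        ix, iy = int(round(x)), int(round(y))
        if 0 <= iy < H and 0 <= ix < W and mask.mask[iy, ix]:
            in_mask.append(est)
    beating = [e for e in in_mask if e.is_beating]
    area = len(beating) * grid.spacing**2
    mask_area = mask.area_px2
    freqs = [e.frequency for e in beating]
    if not in_mask:
        logger.warning("aggregate_well: no grid points fall inside the cell mask")
    return WellBeatResult(
        estimates=in_mask,
        grid=grid,
        beating_area_px2=float(area),
        beating_area_pct_of_mask=float(100.0 * area / mask_area) if mask_area else 0.0,
        beating_area_pct_of_roi=(
            float(100.0 * area / roi_area_px2) if roi_area_px2 else float("nan")
        ),
        mean_frequency=float(np.mean(freqs)) if freqs else None,
        n_points_total=len(estimates),
        n_points_in_mask=len(in_mask),
        n_points_beating=len(beating),
    )


def render_heatmap(
    result: WellBeatResult,
    shape: tuple[int, int],
    f_range: tuple[float, float] = (0.0, DEFAULT_F_MAX),
    cmap_name: str = "viridis",
) -> np.ndarray:
    """RGB uint8 raster with each beating point's lattice cell colour-coded
    by its frequency; non-beating/out-of-mask cells stay background (black).

    Deterministic for a fixed input: the colour ramp is a fixed matplotlib
    colormap over ``f_range`` beats/s.
    """
    import matplotlib

    cmap = matplotlib.colormaps[cmap_name]
    H, W = shape
    img = np.zeros((H, W, 3), dtype=np.uint8)
    half = result.grid.spacing / 2.0
    lo, hi = f_range
    for est in result.estimates:
        if not est.is_beating:
            continue
        x, y = est.position
        y0, y1 = int(max(0, round(y - half))), int(min(H, round(y + half)))
        x0, x1 = int(max(0, round(x - half))), int(min(W, round(x + half)))
        t = 0.0 if hi <= lo else float(np.clip((est.frequency - lo) / (hi - lo), 0, 1))
        rgba = cmap(t)
        img[y0:y1, x0:x1] = tuple(int(255 * c) for c in rgba[:3])
    return img
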