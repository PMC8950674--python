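"""Reference-point grids, sparse Lucas-Kanade tracking, distance profiles.

The contraction of a cardiomyocyte monolayer is measured at a lattice of
reference points (20 px apart by default).  Each point is tracked frame by
frame with a pyramidal Lucas-Kanade solver: the local displacement that
minimises the windowed intensity residual between consecutive frames,
refined coarse-to-fine over an image pyramid.  A point's *distance profile*
d(t) is its Euclidean distance from the first-frame position; inter-frame
steps below a noise threshold ``alpha`` are zeroed (position held) so that
sub-threshold jitter contributes nothing to the profile.

``block_matching_track`` is a deliberately naive exhaustive integer-search
tracker kept as an independent cross-check of the flow solver; it is never
used in the analysis pipeline itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .video_io import DegenerateInputError, VideoClip

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "TrackedPoint",
    "DistanceProfile",
    "LostPointError",
    "place_reference_grid",
    "track_points",
    "distance_profile",
    "block_matching_track",
    "profiles_to_frame",
]

#: default spacing of the reference-point lattice, px
DEFAULT_SPACING = 20


class LostPointError(ValueError):
    """A lost point was passed where a tracked one is required."""


@dataclass(frozen=True)
class GridSpec:
    """Square lattice of reference points.

    ``spacing`` is the inter-point distance in pixels; ``margin`` is the
    distance of the outermost points from the image border (defaults to
    spacing/2, which centres the lattice).
    """

    spacing: float = DEFAULT_SPACING
    margin: float | None = None

    def __post_init__(self) -> None:
        if self.spacing < 2:
            raise ValueError(f"spacing must be >= 2 px, got {self.spacing}")

    @property
    def effective_margin(self) -> float:
        return self.spacing / 2 if self.margin is None else self.margin


@dataclass
class TrackedPoint:
    """One reference point with its per-frame position estimates.

    ``trajectory`` has shape (T, 2) in (x, y) pixel coordinates, sub-pixel
    precision; ``trajectory[0]`` equals ``origin``.  ``status`` is
    ``"tracked"`` or ``"lost"`` (flow solve failed or the point left the
    frame; lost points are excluded from all downstream statistics).
    """

    point_id: int
    origin: tuple[float, float]
    trajectory: np.ndarray
    status: str = "tracked"


@dataclass
class DistanceProfile:
    """Noise-thresholded distance-from-origin profile of one tracked point.

    ``d[t]`` is the Euclidean distance of the (threshold-rebuilt) position
    from the origin at frame t; ``step[t]`` the raw displacement magnitude
    between frames t-1 and t (step[0] = 0).  Every step retained in the
    rebuilt profile is >= ``alpha``.
    """

    point_id: int
    d: np.ndarray
    step: np.ndarray
    alpha: float


def place_reference_grid(width: int, height: int, grid: GridSpec | None = None) -> np.ndarray:
    """Return lattice origins as an (N, 2) array of (x, y), row-major order.

    Points sit at (margin + i*spacing, margin + j*spacing) for every i, j
    that stays strictly inside the frame.
    """
    grid = grid or GridSpec()
    if width <= 0 or height <= 0:
        raise DegenerateInputError("frame dimensions must be positive")
    m, s = grid.effective_margin, grid.spacing
    xs = np.arange(m, width, s, dtype=float)
    xs = xs[xs <= width - 1]
    ys = np.arange(m, height, s, dtype=float)
    ys = ys[ys <= height - 1]
    if xs.size == 0 or ys.size == 0:
        raise DegenerateInputError(
            f"no grid point fits in a {width}x{height} frame with spacing {s}, margin {m}"
        )
    gx, gy = np.meshgrid(xs, ys)  # row-major: y outer, x inner
    return np.column_stack([gx.ravel(), gy.ravel()])


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade
# ---------------------------------------------------------------------------


def _build_pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(1, levels):
        prev = ndimage.gaussian_filter(pyr[-1], sigma=1.0)
        pyr.append(prev[::2, ::2])
    return pyr


def _sample(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _lk_step(
    prev_pyr: list[np.ndarray],
    prev_grad: list[tuple[np.ndarray, np.ndarray]],
    next_pyr: list[np.ndarray],
    pts: np.ndarray,
    window: int,
    max_iter: int = 10,
    tol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """One frame-to-frame LK solve for all points at once.

    Returns (new_positions (P,2) x/y, ok (P,) bool).
    """
    half = window // 2
    off = np.arange(-half, half + 1, dtype=float)
    ox, oy = np.meshgrid(off, off)
    ox, oy = ox.ravel(), oy.ravel()  # (K,)

    P = pts.shape[0]
    disp = np.zeros((P, 2))  # accumulated displacement at full resolution
    ok = np.ones(P, dtype=bool)

    for level in range(len(prev_pyr) - 1, -1, -1):
        scale = 2.0**level
        I, (gy, gx) = prev_pyr[level], prev_grad[level]
        J = next_pyr[level]
        p = pts / scale  # (P,2) x/y at this level
        wx = p[:, 0:1] + ox[None, :]
        wy = p[:, 1:2] + oy[None, :]
        tmpl = _sample(I, wy.ravel(), wx.ravel()).reshape(P, -1)
        Ix = _sample(gx, wy.ravel(), wx.ravel()).reshape(P, -1)
        Iy = _sample(gy, wy.ravel(), wx.ravel()).reshape(P, -1)
        Gxx = (Ix * Ix).sum(axis=1)
        Gxy = (Ix * Iy).sum(axis=1)
        Gyy = (Iy * Iy).sum(axis=1)
        det = Gxx * Gyy - Gxy * Gxy
        solvable = det > 1e-9
        d = disp / scale
        for _ in range(max_iter):
            jx = wx + d[:, 0:1]
            jy = wy + d[:, 1:2]
            cur = _sample(J, jy.ravel(), jx.ravel()).reshape(P, -1)
            err = cur - tmpl
            bx = (err * Ix).sum(axis=1)
            by = (err * Iy).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                dx = -(Gyy * bx - Gxy * by) / det
                dy = -(-Gxy * bx + Gxx * by) / det
            dx = np.where(solvable, dx, 0.0)
            dy = np.where(solvable, dy, 0.0)
            d[:, 0] += dx
            d[:, 1] += dy
            if float(np.nanmax(np.abs(np.concatenate([dx, dy])))) < tol:
                break
        ok &= solvable | (level > 0)  # only demand solvability at the finest level
        disp = d * scale

    new = pts + disp
    ok &= np.all(np.isfinite(new), axis=1)
    return new, ok


def track_points(
    clip: VideoClip,
    origins: np.ndarray,
    window: int = 21,
    pyramid_levels: int = 3,
) -> list[TrackedPoint]:
    """Track each origin through the clip with pyramidal Lucas-Kanade.

    ``window`` is the side of the square correlation window (odd, >= 5).
    Points whose 2x2 normal matrix becomes singular or that leave the frame
    are flagged ``lost``; their count is logged.
    """
    if clip.n_frames < 2:
        raise DegenerateInputError("tracking needs at least 2 frames")
    if window < 5 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 5, got {window}")
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    H, W = clip.height, clip.width
    if np.any(origins[:, 0] < 0) or np.any(origins[:, 0] > W - 1) or np.any(
        origins[:, 1] < 0
    ) or np.any(origins[:, 1] > H - 1):
        raise ValueError("all origins must lie inside the frame")

    gray = clip.gray_frames()
    T, P = clip.n_frames, origins.shape[0]
    traj = np.zeros((T, P, 2))
    traj[0] = origins
    alive = np.ones(P, dtype=bool)

    prev_pyr = _build_pyramid(gray[0], pyramid_levels)
    prev_grad = [np.gradient(lv) for lv in prev_pyr]
    for t in range(1, T):
        next_pyr = _build_pyramid(gray[t], pyramid_levels)
        new, ok = _lk_step(prev_pyr, prev_grad, next_pyr, traj[t - 1], window)
        inside = (
            (new[:, 0] >= 0) & (new[:, 0] <= W - 1) & (new[:, 1] >= 0) & (new[:, 1] <= H - 1)
        )
        alive &= ok & inside
        traj[t] = np.where(alive[:, None], new, traj[t - 1])
        prev_pyr = next_pyr
        prev_grad = [np.gradient(lv) for lv in prev_pyr]

    n_lost = int((~alive).sum())
    if n_lost:
        logger.info("track_points: %d of %d points lost", n_lost, P)
    return [
        TrackedPoint(
            point_id=i,
            origin=(float(origins[i, 0]), float(origins[i, 1])),
            trajectory=traj[:, i, :].copy(),
            status="tracked" if alive[i] else "lost",
        )
        for i in range(P)
    ]


def distance_profile(tp: TrackedPoint, alpha: float = 0.05) -> DistanceProfile:
    """Build the noise-thresholded distance profile of a tracked point.

    Raw inter-frame steps with magnitude < ``alpha`` are zeroed and the
    position held (zero-and-hold), then d(t) is measured from the rebuilt
    positions.  ``alpha=0`` reproduces the raw profile exactly.
    """
    if tp.status != "tracked":
        raise LostPointError(f"point {tp.point_id} was lost during tracking")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    traj = np.asarray(tp.trajectory, dtype=float)
    steps = np.diff(traj, axis=0)
    mags = np.linalg.norm(steps, axis=1)
    keep = mags >= alpha
    rebuilt = np.vstack([traj[0], traj[0] + np.cumsum(steps * keep[:, None], axis=0)])
    d = np.linalg.norm(rebuilt - traj[0], axis=1)
    step = np.concatenate([[0.0], mags])
    return DistanceProfile(point_id=tp.point_id, d=d, step=step, alpha=alpha)


# ---------------------------------------------------------------------------
# independent reference tracker
# ---------------------------------------------------------------------------


def block_matching_track(
    clip: VideoClip,
    origins: np.ndarray,
    window: int = 21,
    search: int = 5,
) -> list[TrackedPoint]:
    """Exhaustive integer block-matching tracker (validation reference only).

    For every frame pair the template window around the current integer
    position is compared by SSD against every integer displacement within
    +/- ``search`` px; the minimum wins, ties broken by smallest
    displacement magnitude then lexicographic (dy, dx).  Brute force and
    integer-resolution by design: a slow, simple cross-check for the
    Lucas-Kanade solver, not part of the analysis pipeline.
    """
    gray = clip.gray_frames()
    T = clip.n_frames
    half = window // 2
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    cands = [(dy, dx) for dy in range(-search, search + 1) for dx in range(-search, search + 1)]
    cands.sort(key=lambda c: (c[0] ** 2 + c[1] ** 2, c))
    out = []
    for i, (x0, y0) in enumerate(origins):
        x, y = int(round(x0)), int(round(y0))
        traj = np.zeros((T, 2))
        traj[0] = (x, y)
        status = "tracked"
        for t in range(1, T):
            if not (
                half <= y < gray.shape[1] - half and half <= x < gray.shape[2] - half
            ):
                status = "lost"
                traj[t:] = (x, y)
                break
            tmpl = gray[t - 1, y - half : y + half + 1, x - half : x + half + 1]
            best, best_ssd = None, np.inf
            for dy, dx in cands:
                ny, nx = y + dy, x + dx
                if not (
                    half <= ny < gray.shape[1] - half and half <= nx < gray.shape[2] - half
                ):
                    continue
                patch = gray[t, ny - half : ny + half + 1, nx - half : nx + half + 1]
                ssd = float(((patch - tmpl) ** 2).sum())
                if ssd < best_ssd - 1e-9:  # strict improvement; cands pre-sorted for ties
                    best_ssd, best = ssd, (dy, dx)
            if best is None:
                status = "lost"
                traj[t:] = (x, y)
                break
            y, x = y + best[0], x + best[1]
            traj[t] = (x, y)
        out.append(TrackedPoint(point_id=i, origin=(float(x0), float(y0)), trajectory=traj, status=status))
    return out


def profiles_to_frame(profiles: list[DistanceProfile], frame_rate: float) -> pd.DataFrame:
    """Long-format export: point_id, frame, t_seconds, d_px."""
    rows = []
    for p in profiles:
        t = np.arange(p.d.size)
        rows.append(
            pd.DataFrame(
                {
                    "point_id": p.point_id,
                    "frame": t,
                    "t_seconds": t / frame_rate,
                    "d_px": p.d,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
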