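"""Seeded generators for ground-truthed synthetic well videos and plates.

The video generator emulates what the beating-analysis pipeline actually
sees: a circular well rim, a textured cell layer that is darker than the
surrounding medium, a contracting sub-region displaced by a smooth pulsating
field, immobile dark specks (dead cells / debris), and additive sensor
noise.  The displacement of a point at depth-weight w follows

    u(x, t) = amplitude * sin(pi * f * t) * w(x) * direction,

so its distance-from-origin profile is amplitude * |sin(pi f t)| * w — one
contraction excursion per beat, i.e. exactly ``f`` peaks per second.  The
weight w ramps linearly from 0 at the beating-region boundary to 1 at
``taper`` px depth, which keeps all motion strictly inside the region.

The plate generator draws per-well raw fluorescence readings from a known
four-parameter log-logistic (4PL) concentration-response curve with
multiplicative Gaussian noise of a stated CoV, laid out on the 48-well
test-plate design.  Both generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose_response import build_plate_layout, serial_dilution
from .video_io import VideoClip

__all__ = [
    "SyntheticWellSpec",
    "SyntheticPlateSpec",
    "generate_well_video",
    "generate_plate",
    "four_pl",
]


@dataclass
class SyntheticWellSpec:
    """Parameters of a synthetic beating-well video.

    Defaults describe the validation conditions used throughout the test
    suite: 30 fps, 10 s, 3 px contraction amplitude, mild sensor noise.
    """

    width: int = 256
    height: int = 256
    well_radius: float | None = None  # default 0.45 * min(W, H)
    cell_radius: float | None = None  # default 0.88 * well_radius
    beating_radius: float | None = None  # default 0.6 * cell_radius
    frequency: float = 1.5  # beats/s
    amplitude: float = 3.0  # px
    taper: float = 4.0  # px ramp width of the displacement weight
    texture_scale: float = 2.5  # px, band-limit of the cell texture
    n_specks: int = 5
    speck_radius: float = 2.0
    speck_margin: float = 12.0  # min distance of specks from the beating region
    noise_sigma: float = 2.0  # intensity units on the 0-255 scale
    frame_rate: float = 30.0
    duration: float = 10.0  # seconds
    seed: int = 0

    def resolved(self) -> "SyntheticWellSpec":
        s = SyntheticWellSpec(**{**self.__dict__})
        m = min(s.width, s.height)
        if s.well_radius is None:
            s.well_radius = 0.45 * m
        if s.cell_radius is None:
            s.cell_radius = 0.88 * s.well_radius
        if s.beating_radius is None:
            s.beating_radius = 0.6 * s.cell_radius
        return s


def _disc(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def generate_well_video(spec: SyntheticWellSpec) -> tuple[VideoClip, dict]:
    """Render the synthetic well video and return (clip, ground_truth).

    ground_truth holds the cell/beating masks, the core mask (weight ~ 1),
    the weight field, the beat frequency and the amplitude.  Raises on a
    beat frequency at or above Nyquist.
    """
    spec = spec.resolved()
    if spec.frequency >= spec.frame_rate / 2.0:
        raise ValueError(
            f"frequency {spec.frequency} >= Nyquist ({spec.frame_rate / 2})"
        )
    H, W = spec.height, spec.width
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    rng = np.random.default_rng(spec.seed)

    well = _disc(H, W, cx, cy, spec.well_radius)
    cells = _disc(H, W, cx, cy, spec.cell_radius)
    beating = _disc(H, W, cx, cy, spec.beating_radius)

    # base scene: bright medium, darker band-limited cell texture, dark rim
    base = np.full((H, W), 235.0)
    base[well] = 220.0  # medium inside the well, outside the cell layer
    texture = ndimage.gaussian_filter(rng.normal(size=(H, W)), spec.texture_scale)
    texture = texture / max(texture.std(), 1e-9)
    base[cells] = np.clip(84.0 + 13.0 * texture[cells], 30.0, 150.0)
    rim = _disc(H, W, cx, cy, spec.well_radius + 1.5) & ~_disc(
        H, W, cx, cy, spec.well_radius - 1.5
    )
    base[rim] = 40.0

    # displacement weight: 0 at the beating boundary, 1 at >= taper depth
    dist_in = ndimage.distance_transform_edt(beating)
    weight = np.clip(dist_in / max(spec.taper, 1e-9), 0.0, 1.0)

    # immobile specks in the cell layer, kept clear of the beating region so
    # a tracking window over moving tissue never contains a static artifact
    speck_zone = cells & ~_disc(
        H, W, cx, cy, spec.beating_radius + spec.speck_margin
    )
    zy, zx = np.nonzero(speck_zone)
    speck_mask = np.zeros((H, W), dtype=bool)
    if spec.n_specks and zy.size:
        pick = rng.choice(zy.size, size=min(spec.n_specks, zy.size), replace=False)
        for j in pick:
            speck_mask |= _disc(H, W, float(zx[j]), float(zy[j]), spec.speck_radius)

    n_frames = int(round(spec.duration * spec.frame_rate))
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    dirx, diry = np.cos(np.pi / 4), np.sin(np.pi / 4)
    frames = np.empty((n_frames, H, W), dtype=np.uint8)
    for t in range(n_frames):
        s = spec.amplitude * np.sin(np.pi * spec.frequency * t / spec.frame_rate)
        if s == 0.0:
            warped = base.copy()
        else:
            ux = s * weight * dirx
            uy = s * weight * diry
            warped = ndimage.map_coordinates(
                base, [yy - uy, xx - ux], order=3, mode="nearest"
            )
        warped[speck_mask] = 45.0
        noisy = warped + rng.normal(0.0, spec.noise_sigma, size=(H, W))
        frames[t] = np.clip(noisy, 0, 255).astype(np.uint8)

    clip = VideoClip(frames=frames, frame_rate=spec.frame_rate)
    ground_truth = {
        "well_center": (cx, cy),
        "well_radius": spec.well_radius,
        "cell_mask": cells,
        "beating_mask": beating,
        "core_mask": weight >= 0.999,
        "weight": weight,
        "speck_mask": speck_mask,
        "frequency": spec.frequency,
        "amplitude": spec.amplitude,
    }
    return clip, ground_truth


# ---------------------------------------------------------------------------
# simulated concentration-response plates
# ---------------------------------------------------------------------------


def four_pl(c, upper: float, lower: float, ec50: float, slope: float):
    """Four-parameter log-logistic response (% scale), defined at c = 0."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        r = lower + (upper - lower) / (1.0 + np.exp(slope * (np.log(c) - np.log(ec50))))
    return np.where(c == 0, upper, r)


@dataclass
class SyntheticPlateSpec:
    """Parameters of a simulated 48-well concentration-response plate.

    Defaults mirror the study design: six concentrations in a 1:3 serial
    dilution in quadruplicate, a known 4PL curve, multiplicative response
    noise with a stated CoV (16% matches the viability controls), and raw
    fluorescence levels bracketed by background and solvent controls.
    """

    top_conc: float = 3.0  # µM
    dilution_fold: float = 3.0
    n_conc: int = 6
    upper: float = 100.0
    lower: float = 0.0
    ec50: float = 0.7  # µM
    slope: float = 2.0
    noise_cov: float = 16.0  # % multiplicative CoV
    sc_raw: float = 1000.0  # solvent-control fluorescence level
    bc_raw: float = 100.0  # background fluorescence level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conc < 2:
            raise ValueError("need n_conc >= 2")
        if self.noise_cov < 0:
            raise ValueError("CoV must be >= 0")

    def curve(self, c):
        return four_pl(c, self.upper, self.lower, self.ec50, self.slope)


def generate_plate(spec: SyntheticPlateSpec, endpoint: str = "viability") -> pd.DataFrame:
    """Simulate one plate; returns tidy per-well rows.

    Columns: well, row, col, role, concentration_uM, endpoint, raw_value,
    true_response_pct.  Treatment and SC responses are curve(c) x (1 + eps)
    with eps ~ N(0, CoV/100); BC and LC wells get the same multiplicative
    noise on their raw levels.  Water wells carry no reading (NaN).
    """
    layout = build_plate_layout()
    series = serial_dilution(spec.top_conc, spec.dilution_fold, spec.n_conc)
    # C1 is the lowest concentration, C{n} the highest
    conc_by_role = {
        f"C{i + 1}": series.concentrations[spec.n_conc - 1 - i] for i in range(spec.n_conc)
    }
    rng = np.random.default_rng(spec.seed)
    span = spec.sc_raw - spec.bc_raw
    rows = []
    for rec in layout.table.itertuples(index=False):
        role = rec.role
        conc = conc_by_role.get(role, 0.0)
        if role == "WATER":
            raw = np.nan
            true_resp = np.nan
        elif role == "BC":
            raw = spec.bc_raw * (1.0 + rng.normal(0.0, spec.noise_cov / 100.0))
            true_resp = 0.0
        elif role == "LC":
            # lysed wells read just above background
            raw = 1.05 * spec.bc_raw * (1.0 + rng.normal(0.0, spec.noise_cov / 100.0))
            true_resp = 0.0
        else:  # SC or a concentration
            resp = float(spec.curve(conc)) * (
                1.0 + rng.normal(0.0, spec.noise_cov / 100.0)
            )
            raw = spec.bc_raw + resp / 100.0 * span
            true_resp = float(spec.curve(conc))
        rows.append(
            {
                "well": rec.well,
                "row": rec.row,
                "col": rec.col,
                "role": role,
                "concentration_uM": conc,
                "endpoint": endpoint,
                "raw_value": raw,
                "true_response_pct": true_resp,
            }
        )
    return pd.DataFrame(rows)


def true_bmc(spec: SyntheticPlateSpec, bmr: int) -> float:
    """Closed-form inverse of the generating 4PL at the benchmark level."""
    target = spec.upper * (1.0 - bmr / 100.0)
    frac = (spec.upper - spec.lower) / (target - spec.lower) - 1.0
    return float(spec.ec50 * frac ** (1.0 / spec.slope))
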