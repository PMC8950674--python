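"""Concentration-response statistics for the embryotoxicity endpoints.

Covers the plate design (48-well, 1:3 serial dilution in quadruplicate with
an edge-effect aware layout), viability normalisation against background and
solvent controls, selection of the benchmark response (BMR) level from the
coefficient of variation of the controls, least-squares fitting of a pool of
13 concentration-response families (linear, sigmoidal, monotone and
non-monotone trends), small-sample-corrected information-criterion model
selection, benchmark concentration (BMC) estimation with bootstrap
confidence limits (BMCL/BMCU), and the specific/unspecific/borderline
classification of an endpoint by the overlap of its BMC confidence interval
with the viability interval.

The BMC at BMR = 50 equals the IC50 (viability) or ID50 (differentiation
endpoints) of the classical reporting convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "DilutionSeries",
    "PlateLayout",
    "FittedCurve",
    "BMCResult",
    "EndpointClassification",
    "InvalidPlateError",
    "NoFitError",
    "serial_dilution",
    "build_plate_layout",
    "normalize_viability",
    "compute_cov",
    "select_bmr",
    "MODEL_POOL",
    "fit_candidates",
    "select_model",
    "compute_bmc",
    "classify_endpoint",
]

ROWS = "ABCDEF"
COLS = range(1, 9)


class InvalidPlateError(ValueError):
    """Plate controls are inconsistent (e.g. solvent signal <= background)."""


class NoFitError(RuntimeError):
    """No model in the pool converged on the data."""


# ---------------------------------------------------------------------------
# dilution series and plate layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DilutionSeries:
    """Geometric dilution series, highest concentration first (µM)."""

    top: float
    fold: float
    n: int
    concentrations: tuple[float, ...]

    @property
    def display(self) -> tuple[str, ...]:
        """Concentrations rounded to 2 significant figures for reporting."""
        return tuple(f"{c:.2g}" for c in self.concentrations)


def serial_dilution(top: float, fold: float = 3.0, n: int = 6) -> DilutionSeries:
    """Exact geometric series top, top/fold, ..., top/fold^(n-1).

    Full precision is kept for computation; :attr:`DilutionSeries.display`
    rounds to 2 significant figures for reporting.
    """
    if top <= 0 or fold <= 1 or n < 1:
        raise ValueError("need top > 0, fold > 1, n >= 1")
    conc = tuple(top / fold**i for i in range(n))
    return DilutionSeries(top=top, fold=fold, n=n, concentrations=conc)


@dataclass
class PlateLayout:
    """Role map of the 48-well test plate.

    Roles: ``C1``..``C6`` (concentrations, C1 lowest, quadruplicate), ``SC``
    (solvent control), ``LC`` (lysis control), ``BC`` (background control),
    ``WATER`` (border wells).  The solvent control and the lowest
    concentration each place exactly one replicate on a plate-edge well so
    edge effects can be checked against the interior replicates.
    """

    table: pd.DataFrame  # columns: well, row, col, role

    def roles(self) -> pd.Series:
        return self.table.set_index("well")["role"]

    def is_edge(self, row: str, col: int) -> bool:
        return row in (ROWS[0], ROWS[-1]) or col in (COLS[0], COLS[-1])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        return cls(table=pd.read_csv(path))


def build_plate_layout() -> PlateLayout:
    """Deterministic 48-well (6 rows x 8 cols) layout.

    24 treatment wells (6 concentrations x 4), 4 SC, 2 LC, 2 BC, 16 water
    border wells.  SC and C1 have exactly one edge replicate each; the two
    treatment replicates that cannot fit in the 24-well interior are
    assigned to the top concentration C6, where edge effects matter least
    for low-dose inference.
    """
    assign: dict[tuple[str, int], str] = {}

    def put(role: str, *wells: tuple[str, int]) -> None:
        for w in wells:
            assign[w] = role

    put("SC", ("B", 2), ("C", 2), ("D", 2), ("A", 2))
    put("C1", ("B", 3), ("C", 3), ("D", 3), ("A", 3))
    put("C2", ("E", 2), ("E", 3), ("B", 4), ("C", 4))
    put("C3", ("D", 4), ("E", 4), ("B", 5), ("C", 5))
    put("C4", ("D", 5), ("E", 5), ("B", 6), ("C", 6))
    put("C5", ("D", 6), ("E", 6), ("B", 7), ("C", 7))
    put("C6", ("D", 7), ("E", 7), ("A", 7), ("F", 7))
    put("LC", ("B", 1), ("C", 1))
    put("BC", ("D", 1), ("E", 1))

    records = []
    for r in ROWS:
        for c in COLS:
            role = assign.get((r, c), "WATER")
            records.append({"well": f"{r}{c}", "row": r, "col": c, "role": role})
    return PlateLayout(table=pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# normalisation, CoV, BMR
# ---------------------------------------------------------------------------


def normalize_viability(raw: pd.DataFrame, lc_tolerance: float = 0.25) -> pd.DataFrame:
    """Normalise raw per-well readings to % of the solvent control.

    ``raw`` is tidy with at least columns ``role`` and ``raw_value`` (other
    columns pass through).  value = (raw - mean(BC)) / (mean(SC) - mean(BC))
    x 100.  LC wells are a QC check only (they must fall near the
    background; a deviation beyond ``lc_tolerance`` of the dynamic range is
    logged) and never enter the denominator.
    """
    roles = raw["role"]
    sc = raw.loc[roles == "SC", "raw_value"].to_numpy(float)
    bc = raw.loc[roles == "BC", "raw_value"].to_numpy(float)
    if sc.size < 1 or bc.size < 1:
        raise InvalidPlateError("need at least one SC and one BC well")
    sc_mean, bc_mean = sc.mean(), bc.mean()
    if sc_mean <= bc_mean:
        raise InvalidPlateError(
            f"mean(SC)={sc_mean:.3g} <= mean(BC)={bc_mean:.3g}: invalid plate"
        )
    span = sc_mean - bc_mean
    lc = raw.loc[roles == "LC", "raw_value"].to_numpy(float)
    if lc.size and abs(lc.mean() - bc_mean) > lc_tolerance * span:
        logger.warning(
            "lysis control far from background (LC=%.3g, BC=%.3g): check plate",
            lc.mean(),
            bc_mean,
        )
    out = raw.copy()
    out["value_pct"] = (out["raw_value"].astype(float) - bc_mean) / span * 100.0
    return out


def compute_cov(control_values: Sequence[float]) -> float:
    """Coefficient of variation of the controls: sample SD / mean x 100."""
    vals = np.asarray(control_values, dtype=float)
    if vals.size < 2:
        raise ValueError("CoV needs at least 2 values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("CoV undefined for zero-mean values")
    return float(vals.std(ddof=1) / abs(mean) * 100.0)


def select_bmr(cov: float) -> int:
    """Benchmark-response level from the control CoV.

    The CoV is rounded up to the next 10% step and clamped to [20, 50]: a
    very quiet endpoint still gets the broader BMR 20, a very noisy one is
    capped at BMR 50 (the IC50/ID50 level).
    """
    if cov < 0:
        raise ValueError("CoV must be >= 0")
    return int(min(50, max(20, 10 * np.ceil(cov / 10.0))))


# ---------------------------------------------------------------------------
# the 13-family concentration-response pool
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFamily:
    """One candidate concentration-response function family."""

    name: str
    n_params: int
    fn: Callable[..., np.ndarray]
    p0: Callable[[np.ndarray, np.ndarray], np.ndarray]
    bounds: tuple[tuple[float, ...], tuple[float, ...]]


def _hi_lo_e0(c: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    order = np.argsort(c)
    hi = float(np.mean(y[c == c.min()])) if (c == 0).any() else float(y[order][:4].mean())
    lo = float(np.mean(y[c == c.max()]))
    pos = np.unique(c[c > 0])
    e0 = float(np.sqrt(pos.min() * pos.max())) if pos.size else 1.0
    # concentration nearest the half response, if the curve actually drops
    half = (hi + lo) / 2.0
    for cc in pos:
        if np.mean(y[c == cc]) <= half:
            e0 = float(cc)
            break
    return hi, lo, e0


def _safe_log(c: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(np.asarray(c, dtype=float))


def _pow_ratio(c: np.ndarray, e: float, b: float) -> np.ndarray:
    """(c/e)^b with the b>0-style limit 0 at c=0 handled explicitly."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        r = np.exp(b * (_safe_log(c) - np.log(e)))
    return np.where(c == 0, 0.0 if b > 0 else np.inf, r)


def _f_linear(c, a, b):
    return a + b * np.asarray(c, float)


def _f_quadratic(c, a, b, d):
    c = np.asarray(c, float)
    return a + b * c + d * c**2


def _f_exp_decay(c, a, e):
    return a * np.exp(-np.asarray(c, float) / e)


def _f_ll2(c, b, e):
    return 100.0 / (1.0 + _pow_ratio(c, e, b))


def _f_ll3(c, b, d, e):
    return d / (1.0 + _pow_ratio(c, e, b))


def _f_ll4(c, b, lo, hi, e):
    return lo + (hi - lo) / (1.0 + _pow_ratio(c, e, b))


def _f_ll5(c, b, lo, hi, e, g):
    return lo + (hi - lo) / (1.0 + _pow_ratio(c, e, b)) ** g


def _f_weibull1(c, b, lo, hi, e):
    c = np.asarray(c, float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        t = np.exp(np.clip(b * (_safe_log(c) - np.log(e)), -700, 700))
    t = np.where(c == 0, 0.0 if b > 0 else np.inf, t)
    return lo + (hi - lo) * np.exp(-t)


def _f_weibull2(c, b, lo, hi, e):
    c = np.asarray(c, float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        t = np.exp(np.clip(b * (_safe_log(c) - np.log(e)), -700, 700))
    t = np.where(c == 0, 0.0 if b > 0 else np.inf, t)
    return lo + (hi - lo) * (1.0 - np.exp(-t))


def _f_asymptotic(c, lo, hi, e):
    return lo + (hi - lo) * np.exp(-np.asarray(c, float) / e)


def _f_mm_decay(c, lo, hi, e):
    c = np.asarray(c, float)
    return hi - (hi - lo) * c / (e + c)


def _f_lognormal_bell(c, a, h, e, s):
    c = np.asarray(c, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (_safe_log(c) - np.log(e)) / s
    out = a + h * np.exp(-0.5 * z**2)
    return np.where(c == 0, a, out)


def _f_cedergreen(c, b, lo, hi, e, f):
    c = np.asarray(c, float)
    with np.errstate(divide="ignore", over="ignore"):
        horm = np.where(c > 0, f * np.exp(-1.0 / c), 0.0)
    return lo + (hi - lo + horm) / (1.0 + _pow_ratio(c, e, b))


_BIG = 1e8


def _make_pool() -> tuple[ModelFamily, ...]:
    inf = np.inf
    return (
        ModelFamily(
            "linear", 2, _f_linear,
            lambda c, y: [float(y.mean()), 0.0],
            ((-_BIG, -_BIG), (_BIG, _BIG)),
        ),
        ModelFamily(
            "quadratic", 3, _f_quadratic,
            lambda c, y: [float(y.mean()), 0.0, 0.0],
            ((-_BIG,) * 3, (_BIG,) * 3),
        ),
        ModelFamily(
            "exp_decay", 2, _f_exp_decay,
            lambda c, y: [_hi_lo_e0(c, y)[0], _hi_lo_e0(c, y)[2]],
            ((0, 1e-9), (_BIG, _BIG)),
        ),
        ModelFamily(
            "log_logistic_2", 2, _f_ll2,
            lambda c, y: [1.0, _hi_lo_e0(c, y)[2]],
            ((1e-3, 1e-9), (50, _BIG)),
        ),
        ModelFamily(
            "log_logistic_3", 3, _f_ll3,
            lambda c, y: [1.0, _hi_lo_e0(c, y)[0], _hi_lo_e0(c, y)[2]],
            ((1e-3, 0, 1e-9), (50, _BIG, _BIG)),
        ),
        ModelFamily(
            "log_logistic_4", 4, _f_ll4,
            lambda c, y: [1.0, _hi_lo_e0(c, y)[1], _hi_lo_e0(c, y)[0], _hi_lo_e0(c, y)[2]],
            ((1e-3, -_BIG, -_BIG, 1e-9), (50, _BIG, _BIG, _BIG)),
        ),
        ModelFamily(
            "log_logistic_5", 5, _f_ll5,
            lambda c, y: [1.0, _hi_lo_e0(c, y)[1], _hi_lo_e0(c, y)[0], _hi_lo_e0(c, y)[2], 1.0],
            ((1e-3, -_BIG, -_BIG, 1e-9, 1e-2), (50, _BIG, _BIG, _BIG, 1e2)),
        ),
        ModelFamily(
            "weibull_1", 4, _f_weibull1,
            lambda c, y: [1.0, _hi_lo_e0(c, y)[1], _hi_lo_e0(c, y)[0], _hi_lo_e0(c, y)[2]],
            ((-50, -_BIG, -_BIG, 1e-9), (50, _BIG, _BIG, _BIG)),
        ),
        ModelFamily(
            "weibull_2", 4, _f_weibull2,
            lambda c, y: [-1.0, _hi_lo_e0(c, y)[1], _hi_lo_e0(c, y)[0], _hi_lo_e0(c, y)[2]],
            ((-50, -_BIG, -_BIG, 1e-9), (50, _BIG, _BIG, _BIG)),
        ),
        ModelFamily(
            "asymptotic_regression", 3, _f_asymptotic,
            lambda c, y: [_hi_lo_e0(c, y)[1], _hi_lo_e0(c, y)[0], _hi_lo_e0(c, y)[2]],
            ((-_BIG, -_BIG, 1e-9), (_BIG, _BIG, _BIG)),
        ),
        ModelFamily(
            "michaelis_menten_decay", 3, _f_mm_decay,
            lambda c, y: [_hi_lo_e0(c, y)[1], _hi_lo_e0(c, y)[0], _hi_lo_e0(c, y)[2]],
            ((-_BIG, -_BIG, 1e-9), (_BIG, _BIG, _BIG)),
        ),
        ModelFamily(
            "lognormal_bell", 4, _f_lognormal_bell,
            lambda c, y: [float(y.min()), float(y.max() - y.min()), _hi_lo_e0(c, y)[2], 1.0],
            ((-_BIG, -_BIG, 1e-9, 1e-3), (_BIG, _BIG, _BIG, 1e3)),
        ),
        ModelFamily(
            "cedergreen_hormesis", 5, _f_cedergreen,
            lambda c, y: [1.0, _hi_lo_e0(c, y)[1], _hi_lo_e0(c, y)[0], _hi_lo_e0(c, y)[2], 1.0],
            ((1e-3, -_BIG, -_BIG, 1e-9, -_BIG), (50, _BIG, _BIG, _BIG, _BIG)),
        ),
    )


MODEL_POOL: tuple[ModelFamily, ...] = _make_pool()
_POOL_ORDER = {m.name: i for i, m in enumerate(MODEL_POOL)}


#: floor of the relative-error scale, in % of control: keeps the weight of
#: near-zero responses finite
SIGMA_FLOOR = 5.0


def _sigma_scale(pred: np.ndarray) -> np.ndarray:
    return np.maximum(np.abs(pred), SIGMA_FLOOR)


@dataclass
class FittedCurve:
    """A converged relative-error least-squares fit of one pool family.

    ``rss`` is the plain residual sum of squares and ``aicc`` the
    small-sample-corrected information criterion built on it.  ``wrss`` is
    the residual sum under the relative-error scale sigma_i =
    max(|f(c_i)|, SIGMA_FLOOR); it calibrates the bootstrap noise (the
    assay states its control variability as a CoV) but deliberately does
    not enter model comparison: a signal-dependent likelihood would reward
    families that predict low responses.
    """

    family: str
    params: np.ndarray
    rss: float
    wrss: float  # relative-error scale; calibrates the bootstrap noise
    n_obs: int
    n_params: int
    aicc: float
    _fn: Callable = field(repr=False)

    def predict(self, conc) -> np.ndarray | float:
        scalar = np.isscalar(conc)
        out = self._fn(np.atleast_1d(np.asarray(conc, dtype=float)), *self.params)
        return float(out[0]) if scalar else out


def _aicc(rss: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_candidates(
    conc: np.ndarray,
    response: np.ndarray,
    pool: Sequence[ModelFamily] = MODEL_POOL,
    irls_passes: int = 0,
) -> list[FittedCurve]:
    """Least-squares fit of every pool family; non-converged fits dropped
    with a log entry.

    ``conc`` (µM, may include 0 for controls) and ``response`` (% of
    control) are flat per-well arrays.  ``irls_passes`` > 0 additionally
    reweights each family by its predicted response (relative-error
    model); the default is ordinary least squares.  Requires >= 4 distinct
    concentrations.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if np.unique(conc).size < 4:
        raise ValueError("need >= 4 distinct concentrations to fit the pool")
    fits: list[FittedCurve] = []
    n = conc.size
    for fam in pool:
        try:
            with np.errstate(all="ignore"):
                popt, _ = optimize.curve_fit(
                    fam.fn,
                    conc,
                    response,
                    p0=fam.p0(conc, response),
                    bounds=fam.bounds,
                    maxfev=20000,
                )
                for _ in range(irls_passes):
                    sig = _sigma_scale(fam.fn(conc, *popt))
                    popt, _ = optimize.curve_fit(
                        fam.fn, conc, response, p0=popt,
                        bounds=fam.bounds, sigma=sig, maxfev=20000,
                    )
            pred = fam.fn(conc, *popt)
            resid = response - pred
            rss = float(np.dot(resid, resid))
            sig = _sigma_scale(pred)
            wrss = float(np.sum((resid / sig) ** 2))
            if not (np.isfinite(rss) and np.isfinite(wrss)):
                raise RuntimeError("non-finite residual")
        except (RuntimeError, ValueError, optimize.OptimizeWarning) as exc:
            logger.debug("fit of %s failed: %s", fam.name, exc)
            continue
        fits.append(
            FittedCurve(
                family=fam.name,
                params=np.asarray(popt),
                rss=rss,
                wrss=wrss,
                n_obs=n,
                n_params=fam.n_params,
                aicc=_aicc(rss, n, fam.n_params),
                _fn=fam.fn,
            )
        )
    if not fits:
        raise NoFitError("no model in the pool converged")
    return fits


def select_model(fits: Sequence[FittedCurve], tol: float = 1e-9) -> FittedCurve:
    """Lowest AICc wins; ties go to fewer parameters, then pool order."""
    if not fits:
        raise NoFitError("empty fit list")
    best = min(f.aicc for f in fits)
    tied = [f for f in fits if f.aicc <= best + tol]
    tied.sort(key=lambda f: (f.n_params, _POOL_ORDER.get(f.family, 99)))
    return tied[0]


# ---------------------------------------------------------------------------
# BMC / BMCL / BMCU and classification
# ---------------------------------------------------------------------------


@dataclass
class BMCResult:
    """Benchmark concentration with bootstrap confidence bounds (µM)."""

    endpoint: str
    bmr: int
    bmc: float | None
    bmcl: float | None
    bmcu: float | None
    model_family: str
    not_reached: bool = False
    cov_controls: float | None = None
    n_boot_used: int = 0
    bootstrap_bmcs: np.ndarray | None = field(default=None, repr=False)

    @property
    def reached(self) -> bool:
        return not self.not_reached and self.bmc is not None


def _solve_bmc(
    predict: Callable[[np.ndarray], np.ndarray],
    target: float,
    c_lo: float,
    c_hi: float,
    n_grid: int = 512,
) -> float | None:
    """First downward crossing of the target level on a log grid, refined
    by bisection.  None when the curve never crosses inside (0, c_hi]."""
    grid = np.geomspace(c_lo, c_hi, n_grid)
    vals = np.asarray(predict(grid), dtype=float)
    above = vals > target
    cross = np.nonzero(above[:-1] & ~above[1:])[0]
    if cross.size == 0:
        # curve may start below target right away (steep drop below c_lo)
        if not above[0]:
            return float(c_lo)
        return None
    i = int(cross[0])

    def gap(c: float) -> float:
        return float(np.asarray(predict(c)).ravel()[0]) - target

    try:
        return float(optimize.brentq(gap, grid[i], grid[i + 1]))
    except ValueError:
        return float(grid[i])


def compute_bmc(
    curve: FittedCurve,
    bmr: int,
    conc: np.ndarray,
    response: np.ndarray,
    endpoint: str = "endpoint",
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed: int = 0,
    cov_controls: float | None = None,
    candidate_fits: Sequence[FittedCurve] | None = None,
    reselect_delta: float = 4.0,
    max_competitors: int = 5,
    control_sem_frac: float | None = None,
) -> BMCResult:
    """BMC solving predicted(BMC) = control x (1 - BMR/100), with a seeded
    parametric bootstrap for the BMCL/BMCU limits.

    The control level is the fitted response at concentration zero.  The
    bootstrap resamples responses from the fitted curves plus Gaussian
    residual noise, refits and recomputes the BMC; the two-sided
    ``ci_level`` percentile interval gives BMCL/BMCU.  When
    ``candidate_fits`` is given, the point estimate is Akaike-weight
    model-averaged over the competitive families (AICc within
    ``reselect_delta`` of the best, at most ``max_competitors``), and every
    bootstrap resample is generated from a weight-drawn competitor and
    refit + reselected, so the interval carries model-selection uncertainty
    as well as sampling noise; otherwise only ``curve``'s family is used.
    When the curve never reaches the benchmark level inside the tested
    range the result is flagged ``not_reached``.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    top = float(conc.max())
    pos = conc[conc > 0]
    c_lo = float(pos.min()) / 100.0

    control = float(curve.predict(0.0))
    target = control * (1.0 - bmr / 100.0)
    bmc = _solve_bmc(curve.predict, target, c_lo, top)
    if bmc is None:
        return BMCResult(
            endpoint=endpoint,
            bmr=bmr,
            bmc=None,
            bmcl=None,
            bmcu=None,
            model_family=curve.family,
            not_reached=True,
            cov_controls=cov_controls,
        )

    if candidate_fits is not None:
        best_aicc = min(f.aicc for f in candidate_fits)
        competitors = sorted(
            (f for f in candidate_fits if f.aicc <= best_aicc + reselect_delta),
            key=lambda f: (f.aicc, f.n_params),
        )[:max_competitors]
    else:
        competitors = [curve]

    if len(competitors) > 1:
        # model-averaged point estimate (Akaike weights over the competitive
        # families): a single selected family with no low-dose shoulder can
        # carry a large systematic BMC bias that averaging dilutes
        ws, bs = [], []
        for f in competitors:
            b_f = _solve_bmc(
                f.predict, float(f.predict(0.0)) * (1.0 - bmr / 100.0), c_lo, top
            )
            if b_f is not None:
                ws.append(np.exp(-0.5 * (f.aicc - competitors[0].aicc)))
                bs.append(b_f)
        if bs:
            bmc = float(np.dot(np.asarray(ws) / np.sum(ws), bs))
    fam_of = {m.name: m for m in MODEL_POOL}
    rng = np.random.default_rng(seed)
    n = conc.size

    # model-averaged parametric bootstrap: each resample is generated from
    # a competitor curve drawn by its Akaike weight, under the fitted
    # relative-error noise model (noise scales with the predicted response;
    # the assay states its control variability as a CoV).  Generating only
    # from the selected family would re-select it almost surely and hide
    # model uncertainty from the interval.
    base_aicc = min(f.aicc for f in competitors)
    gen_w = np.array([np.exp(-0.5 * (f.aicc - base_aicc)) for f in competitors])
    gen_w /= gen_w.sum()
    generators = []
    for f in competitors:
        fv = np.asarray(f.predict(conc), dtype=float)
        sig_f = _sigma_scale(fv)
        dof_f = max(1, f.n_obs - f.n_params)
        generators.append((fv, sig_f, float(np.sqrt(f.wrss / dof_f))))

    boots: list[float] = []
    for _ in range(n_boot):
        gi = int(rng.choice(len(competitors), p=gen_w))
        fv, sig_g, rel_sd_g = generators[gi]
        y_star = fv + sig_g * rng.normal(0.0, rel_sd_g, size=n)
        if control_sem_frac:
            # responses are % of the measured solvent-control mean, whose
            # sampling error rescales the whole plate coherently
            y_star = y_star / (1.0 + rng.normal(0.0, control_sem_frac))
        best_key, best_fn, best_popt = None, None, None
        for base in competitors:
            fam = fam_of[base.family]
            try:
                with np.errstate(all="ignore"):
                    popt, _ = optimize.curve_fit(
                        fam.fn, conc, y_star, p0=base.params,
                        bounds=fam.bounds, maxfev=600,
                    )
            except (RuntimeError, ValueError):
                continue
            resid_b = y_star - fam.fn(conc, *popt)
            aicc = _aicc(float(np.dot(resid_b, resid_b)), n, fam.n_params)
            if not np.isfinite(aicc):
                continue
            key = (aicc, fam.n_params)
            if best_key is None or key < best_key:
                best_key, best_fn, best_popt = key, fam.fn, popt
        if best_key is None:
            continue
        pred = lambda c, f=best_fn, p=best_popt: f(np.atleast_1d(np.asarray(c, float)), *p)
        ctrl_b = float(pred(0.0)[0])
        b = _solve_bmc(pred, ctrl_b * (1.0 - bmr / 100.0), c_lo, top)
        if b is not None:
            boots.append(b)
    if boots:
        q = (1.0 - ci_level) / 2.0
        bmcl, bmcu = np.quantile(boots, [q, 1.0 - q])
        bmcl, bmcu = float(min(bmcl, bmc)), float(max(bmcu, bmc))
    else:
        logger.warning("all bootstrap resamples failed; no CI for %s", endpoint)
        bmcl = bmcu = None
    return BMCResult(
        endpoint=endpoint,
        bmr=bmr,
        bmc=float(bmc),
        bmcl=bmcl,
        bmcu=bmcu,
        model_family=curve.family,
        cov_controls=cov_controls,
        n_boot_used=len(boots),
        bootstrap_bmcs=np.asarray(boots) if boots else None,
    )


@dataclass
class EndpointClassification:
    """Outcome of the CI-overlap comparison against viability."""

    label: str  # specific | unspecific | borderline | not_reached
    overlap_pct: float | None
    direction: str | None  # below | above | straddling


def classify_endpoint(viability: BMCResult, endpoint: BMCResult) -> EndpointClassification:
    """Classify an endpoint by the overlap of its BMC confidence interval
    with the viability interval.

    overlap_pct = 100 x |endpoint CI ∩ viability CI| / endpoint CI width.
    ``specific`` requires zero overlap AND the endpoint CI entirely below
    the viability CI (an effect at lower concentrations than cytotoxicity);
    zero overlap above viability is ``unspecific``.  Overlap >= 10% is
    ``unspecific``; anything in between is ``borderline``.
    """
    if not (viability.reached and endpoint.reached):
        return EndpointClassification(label="not_reached", overlap_pct=None, direction=None)
    if None in (viability.bmcl, viability.bmcu, endpoint.bmcl, endpoint.bmcu):
        return EndpointClassification(label="not_reached", overlap_pct=None, direction=None)
    le, ue = endpoint.bmcl, endpoint.bmcu
    lv, uv = viability.bmcl, viability.bmcu
    width = ue - le
    overlap_len = max(0.0, min(ue, uv) - max(le, lv))
    if width <= 0:  # degenerate endpoint CI: containment decides
        overlap_pct = 100.0 if lv <= le <= uv else 0.0
    else:
        overlap_pct = 100.0 * overlap_len / width
    if ue < lv:
        direction = "below"
    elif le > uv:
        direction = "above"
    else:
        direction = "straddling"
    if overlap_pct >= 10.0:
        label = "unspecific"
    elif overlap_pct > 0.0:
        label = "borderline"
    else:
        label = "specific" if direction == "below" else "unspecific"
    return EndpointClassification(label=label, overlap_pct=overlap_pct, direction=direction)


# ---------------------------------------------------------------------------
# endpoint-level driver
# ---------------------------------------------------------------------------


def analyze_endpoint(
    data: pd.DataFrame,
    endpoint: str = "viability",
    bmr: int | None = None,
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed: int = 0,
) -> tuple[BMCResult, FittedCurve]:
    """Normalised tidy data -> (BMCResult, selected curve) for one endpoint.

    ``data`` must hold columns ``role``, ``concentration_uM`` and
    ``value_pct`` (from :func:`normalize_viability` or equivalent).  The BMR
    defaults to the CoV rule on the solvent-control wells.
    """
    sub = data[data["role"].isin([f"C{i}" for i in range(1, 7)] + ["SC"])]
    conc = np.where(sub["role"].eq("SC"), 0.0, sub["concentration_uM"].astype(float))
    y = sub["value_pct"].to_numpy(float)
    controls = y[conc == 0]
    cov = compute_cov(controls) if controls.size >= 2 else None
    sem_frac = (cov / 100.0) / np.sqrt(controls.size) if cov is not None else None
    if bmr is None:
        if cov is None:
            raise InvalidPlateError("cannot select BMR without >= 2 control wells")
        bmr = select_bmr(cov)
    fits = fit_candidates(conc, y)
    best = select_model(fits)
    res = compute_bmc(
        best,
        bmr,
        conc,
        y,
        endpoint=endpoint,
        n_boot=n_boot,
        ci_level=ci_level,
        seed=seed,
        cov_controls=cov,
        candidate_fits=fits,
        control_sem_frac=sem_frac,
    )
    return res, best
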