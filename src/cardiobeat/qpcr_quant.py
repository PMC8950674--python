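"""Absolute qPCR quantification against a standard dilution series.

Copy numbers are read off a standard curve — a least-squares line of Cq
versus log10(copies/µL) over a 1:10 dilution series (3.75e2 .. 3.75e7
molecules/µL in the reference design) — and normalised to the calnexin
(CANX) reference gene, which is stably expressed in hiPSCs differentiating
along the mesodermal lineage.  Replicate Cq values from independent runs
are averaged on the Cq scale before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StandardCurve",
    "ExpressionResult",
    "STANDARD_SERIES_COPIES",
    "fit_standard_curve",
    "quantify",
    "normalize_to_reference",
    "analyze_expression_table",
]

#: reference 1:10 standard series, molecules/µL
STANDARD_SERIES_COPIES: tuple[float, ...] = tuple(3.75 * 10.0**k for k in range(2, 8))


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Cq = intercept + slope * log10(copies/µL)."""

    slope: float
    intercept: float
    r_squared: float
    cq_min: float
    cq_max: float

    @property
    def efficiency_pct(self) -> float:
        """Amplification efficiency, (10^(-1/slope) - 1) x 100.

        A perfect doubling per cycle gives slope -log2(10) = -3.3219 and
        100% efficiency.
        """
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0


def fit_standard_curve(copies: np.ndarray, cq: np.ndarray) -> StandardCurve:
    """Fit the standard line from paired (copies/µL, Cq) observations.

    Needs >= 3 points spanning >= 2 decades.  A positive slope means the
    series was inverted (more template cannot amplify later) and is an
    error.
    """
    copies = np.asarray(copies, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if copies.size < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    logc = np.log10(copies)
    if logc.max() - logc.min() < 2.0:
        raise ValueError("standard series must span >= 2 decades")
    fit = stats.linregress(logc, cq)
    if fit.slope >= 0:
        raise ValueError(f"positive slope ({fit.slope:.3g}): inverted standard series?")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        cq_min=float(cq.min()),
        cq_max=float(cq.max()),
    )


def quantify(cq: float, curve: StandardCurve, cq_slack: float = 1.0) -> tuple[float, bool]:
    """Copies/µL for a measured Cq: 10^((cq - intercept) / slope).

    Returns (copies, extrapolated).  Cq values more than ``cq_slack``
    cycles outside the calibrated range are refused.
    """
    lo, hi = curve.cq_min - cq_slack, curve.cq_max + cq_slack
    extrapolated = not (curve.cq_min <= cq <= curve.cq_max)
    if not (lo <= cq <= hi):
        raise ValueError(
            f"Cq {cq:.2f} outside calibrated range [{curve.cq_min:.2f}, "
            f"{curve.cq_max:.2f}] ± {cq_slack}"
        )
    if extrapolated:
        logger.warning("Cq %.2f outside the standard range; extrapolating", cq)
    return float(10.0 ** ((cq - curve.intercept) / curve.slope)), extrapolated


def normalize_to_reference(target_copies: float, reference_copies: float) -> float:
    """Copy-number ratio of a target gene to the reference gene (CANX)."""
    if reference_copies <= 0:
        raise ValueError("reference copy number must be positive")
    return float(target_copies / reference_copies)


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    sample: str
    copies_per_uL: float
    reference_copies: float
    normalized_ratio: float
    extrapolated: bool = False


def analyze_expression_table(
    table: pd.DataFrame, reference_gene: str = "CANX"
) -> pd.DataFrame:
    """End-to-end quantification of a tidy qPCR table.

    Input columns: gene, sample, cq, is_standard, standard_copies.
    Replicate Cq values (same gene/sample or same standard point) are
    averaged on the Cq scale before use.  Output columns: gene, sample,
    copies_per_uL, canx_copies, normalized_ratio, extrapolated.
    """
    curves: dict[str, StandardCurve] = {}
    for gene, grp in table[table["is_standard"]].groupby("gene"):
        pts = grp.groupby("standard_copies")["cq"].mean()
        curves[gene] = fit_standard_curve(pts.index.to_numpy(), pts.to_numpy())

    samples = table[~table["is_standard"]]
    mean_cq = samples.groupby(["gene", "sample"])["cq"].mean()
    copies: dict[tuple[str, str], tuple[float, bool]] = {}
    for (gene, sample), cq in mean_cq.items():
        if gene not in curves:
            raise ValueError(f"no standard series for gene {gene!r}")
        copies[(gene, sample)] = quantify(float(cq), curves[gene])

    rows = []
    for (gene, sample), (n, extr) in copies.items():
        if gene == reference_gene:
            continue
        if (reference_gene, sample) not in copies:
            raise ValueError(f"no {reference_gene} measurement for sample {sample!r}")
        ref, ref_extr = copies[(reference_gene, sample)]
        rows.append(
            {
                "gene": gene,
                "sample": sample,
                "copies_per_uL": n,
                "canx_copies": ref,
                "normalized_ratio": normalize_to_reference(n, ref),
                "extrapolated": extr or ref_extr,
            }
        )
    return pd.DataFrame(rows)
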