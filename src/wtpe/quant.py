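"""Deletion-efficiency quantification: gel densitometry and absolute qPCR.

Two complementary readouts:

* **Gel densitometry.**  Band intensity is proportional to mass, and mass to
  molar amount times length, so molar band ratios use length-normalised
  greyscales::

      efficiency = 100 * (Gd/Ld) / (Gd/Ld + Gu/Lu)

  with G the background-corrected greyscale and L the band length in bp of
  the deleted (d) and undeleted (u) products.

* **Absolute qPCR.**  A standard curve CT = slope*log10(copies) + intercept
  is fitted per assay from a serial-dilution series; sample CTs convert to
  absolute copy numbers and::

      efficiency = 100 * copies(deletion junction) / copies(flanking)

  The amplification efficiency of an assay is 10^(-1/slope) - 1 (a slope of
  -1/log10(2) = -3.3219 corresponds to perfect doubling, 100%).

Replicate CTs are arithmetic-averaged before the log-linear conversion.
Efficiencies are not clamped at 100% — the ratio of absolute copies can
exceed it under assay noise and is flagged instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedEfficiencyError


@dataclass(frozen=True)
class GelLane:
    """Background-corrected band greyscales and band lengths for one lane."""

    greyscale_deleted: float
    greyscale_undeleted: float
    len_deleted_bp: int
    len_undeleted_bp: int

    def __post_init__(self) -> None:
        if self.len_deleted_bp <= 0 or self.len_undeleted_bp <= 0:
            raise ValueError("band lengths must be positive")
        if self.greyscale_deleted < 0 or self.greyscale_undeleted < 0:
            raise ValueError("greyscales must be non-negative")


def gel_deletion_efficiency(lane: GelLane) -> float:
    """Length-normalised greyscale ratio, in percent."""
    gd = lane.greyscale_deleted / lane.len_deleted_bp
    gu = lane.greyscale_undeleted / lane.len_undeleted_bp
    if gd + gu == 0:
        raise UndefinedEfficiencyError("both bands have zero greyscale")
    return 100.0 * (gd / (gd + gu))


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of CT against log10(copies) for one assay."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    ct_range: tuple[float, float]
    warnings: tuple[str, ...] = ()

    @property
    def amplification_efficiency(self) -> float:
        """Fractional per-cycle amplification gain; 1.0 means perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(dilution_copies: Sequence[float], cts: Sequence[float]) -> StandardCurve:
    """Fit CT = slope*log10(copies) + intercept from a dilution series."""
    copies = np.asarray(dilution_copies, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if copies.shape != ct.shape:
        raise ValueError("copies and CT arrays differ in length")
    if copies.size < 3:
        raise InsufficientDataError("standard curve needs at least 3 dilution points")
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    res = stats.linregress(np.log10(copies), ct)
    warnings = ()
    if res.slope >= 0:
        warnings = ("non-negative slope: CT should fall as template increases",)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(copies.size),
        ct_range=(float(ct.min()), float(ct.max())),
        warnings=warnings,
    )


def absolute_copies(curve: StandardCurve, ct: float) -> float:
    """Invert the standard curve: copies = 10^((ct - intercept)/slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def is_extrapolated(curve: StandardCurve, ct: float) -> bool:
    """True when a CT lies outside the fitted dilution-series CT range."""
    lo, hi = curve.ct_range
    return ct < lo or ct > hi


@dataclass(frozen=True)
class QpcrSample:
    """Replicate CTs for the deletion-junction and flanking assays."""

    ct_deleted: tuple[float, ...]
    ct_flanking: tuple[float, ...]

    def __post_init__(self) -> None:
        for ct in (*self.ct_deleted, *self.ct_flanking):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError("CT values must be finite and positive")


@dataclass(frozen=True)
class QpcrResult:
    efficiency_pct: float
    copies_deleted: float
    copies_flanking: float
    mean_ct_deleted: float
    mean_ct_flanking: float
    extrapolated: bool
    exceeds_100pct: bool


def qpcr_deletion_efficiency(
    sample: QpcrSample, curve_deleted: StandardCurve, curve_flanking: StandardCurve
) -> QpcrResult:
    """Absolute-copy ratio of deletion-junction to flanking fragment, percent."""
    ct_d = float(np.mean(sample.ct_deleted))
    ct_f = float(np.mean(sample.ct_flanking))
    copies_d = absolute_copies(curve_deleted, ct_d)
    copies_f = absolute_copies(curve_flanking, ct_f)
    if copies_f == 0:
        raise UndefinedEfficiencyError("flanking assay yielded zero copies")
    eff = 100.0 * copies_d / copies_f
    return QpcrResult(
        efficiency_pct=eff,
        copies_deleted=copies_d,
        copies_flanking=copies_f,
        mean_ct_deleted=ct_d,
        mean_ct_flanking=ct_f,
        extrapolated=is_extrapolated(curve_deleted, ct_d)
        or is_extrapolated(curve_flanking, ct_f),
        exceeds_100pct=eff > 100.0,
    )


def gel_table_efficiencies(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the gel formula to a TSV-style table.

    Expected columns: sample, greyscale_deleted, greyscale_undeleted,
    len_deleted_bp, len_undeleted_bp.
    """
    rows = []
    for _, r in table.iterrows():
        lane = GelLane(
            greyscale_deleted=float(r["greyscale_deleted"]),
            greyscale_undeleted=float(r["greyscale_undeleted"]),
            len_deleted_bp=int(r["len_deleted_bp"]),
            len_undeleted_bp=int(r["len_undeleted_bp"]),
        )
        rows.append({"sample": r["sample"], "efficiency_pct": gel_deletion_efficiency(lane)})
    return pd.DataFrame(rows)


def qpcr_table_efficiencies(
    ct_table: pd.DataFrame, dilution_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample qPCR efficiencies from tidy CT and dilution-series tables.

    ``ct_table`` columns: sample, assay in {deleted, flanking}, ct (one row
    per replicate).  ``dilution_table`` columns: assay, copies, ct.
    """
    curves = {}
    for assay, grp in dilution_table.groupby("assay"):
        curves[assay] = fit_standard_curve(grp["copies"].to_numpy(), grp["ct"].to_numpy())
    rows = []
    for sample, grp in ct_table.groupby("sample"):
        qs = QpcrSample(
            ct_deleted=tuple(grp.loc[grp["assay"] == "deleted", "ct"]),
            ct_flanking=tuple(grp.loc[grp["assay"] == "flanking", "ct"]),
        )
        res = qpcr_deletion_efficiency(qs, curves["deleted"], curves["flanking"])
        rows.append(
            {
                "sample": sample,
                "efficiency_pct": res.efficiency_pct,
                "copies_deleted": res.copies_deleted,
                "copies_flanking": res.copies_flanking,
                "extrapolated": res.extrapolated,
                "exceeds_100pct": res.exceeds_100pct,
            }
        )
    return pd.DataFrame(rows)


def replicate_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample s.d. of biological replicates (plumbing for reporting)."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0
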