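"""Quantitative flow cytometry: bead calibration and semi-quantitative MFI scoring.

Antibody-binding capacity (ABC, antibodies bound per cell) is estimated
from a bead standard curve: beads carrying known numbers of IgG
molecules are stained with the same secondary antibody as the cells,
and a log–log linear calibration maps MFI to ABC. Alongside the
absolute scale, a semi-quantitative ordinal scale grades the ratio of
specific to isotype-control MFI into the conventional serology bins
(−, +/−, 1+, 2+, 3+, 4+) at thresholds 3, 10, 30, 50, 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BeadPoint",
    "FlowCalibration",
    "SemiquantLabel",
    "fit_bead_calibration",
    "abc_from_mfi",
    "semiquant_score",
    "fold_expression",
    "analyze_flow",
]


@dataclass(frozen=True)
class BeadPoint:
    abc: float  # known IgG molecules per bead
    mfi: float

    def __post_init__(self) -> None:
        if self.abc <= 0 or self.mfi <= 0:
            raise ValueError("bead ABC and MFI must be positive")


@dataclass(frozen=True)
class FlowCalibration:
    """Fitted log10(ABC) = intercept + slope·log10(MFI) calibration."""

    slope: float
    intercept: float
    r2: float
    slope_se: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("bead calibration slope must be positive (more antibody, more signal)")

    def summary(self) -> str:
        return "\n".join(
            [
                "Bead calibration: log10(ABC) = intercept + slope * log10(MFI)",
                f"  n beads   {self.n_points}",
                f"  slope     {self.slope:.4f} (se {self.slope_se:.4f})",
                f"  intercept {self.intercept:.4f}",
                f"  r^2       {self.r2:.5f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class SemiquantLabel:
    label: str
    ratio: float


# ordinal scale; lower bin edges on the specific/isotype MFI ratio
_SEMIQUANT_BINS = (
    (100.0, "4+"),
    (50.0, "3+"),
    (30.0, "2+"),
    (10.0, "1+"),
)  # a ratio strictly above 3 but below 10 grades "+/-"; at or below 3, "-"


def fit_bead_calibration(points: Sequence[BeadPoint] | None = None, *, linear: bool = False) -> FlowCalibration:
    """Least-squares calibration from a bead panel (≥4 distinct ABC levels).

    Log–log by default (standard for bead kits); ``linear=True`` fits
    ABC on MFI on the raw scale instead and re-expresses the line as an
    equivalent power law only when exact (slope through origin), so the
    log–log model remains the supported path.
    """
    if points is None or len({p.abc for p in points}) < 4:
        raise ValueError("bead calibration needs at least 4 distinct ABC levels")
    if linear:
        x = np.array([p.mfi for p in points])
        y = np.array([p.abc for p in points])
    else:
        x = np.log10([p.mfi for p in points])
        y = np.log10([p.abc for p in points])
    fit = stats.linregress(x, y)
    if linear:
        # report on the log-log scale for a strictly proportional fit
        if abs(fit.intercept) > 1e-9 * max(abs(y.max()), 1.0):
            raise ValueError("linear-scale calibration is only supported for proportional panels")
        return FlowCalibration(
            slope=1.0, intercept=math.log10(fit.slope), r2=float(fit.rvalue) ** 2, n_points=len(points)
        )
    return FlowCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        slope_se=float(fit.stderr),
        n_points=len(points),
    )


def abc_from_mfi(mfi: float, calibration: FlowCalibration) -> float:
    """Antibodies bound per cell for a measured MFI."""
    if mfi <= 0:
        raise ValueError("MFI must be positive")
    return 10.0 ** (calibration.intercept + calibration.slope * math.log10(mfi))


def semiquant_score(specific_mfi: float, isotype_mfi: float) -> SemiquantLabel:
    """Grade specific staining against the isotype control.

    "−" for a ratio ≤ 3, "+/−" below 10, then "1+" ≥ 10, "2+" ≥ 30,
    "3+" ≥ 50 and "4+" ≥ 100; monotone and total in the ratio.
    """
    if isotype_mfi <= 0:
        raise ValueError("isotype MFI must be positive")
    if specific_mfi < 0:
        raise ValueError("specific MFI must be non-negative")
    ratio = specific_mfi / isotype_mfi
    for edge, label in _SEMIQUANT_BINS:
        if ratio >= edge:
            return SemiquantLabel(label=label, ratio=ratio)
    if ratio > 3.0:
        return SemiquantLabel(label="+/-", ratio=ratio)
    return SemiquantLabel(label="-", ratio=ratio)


def fold_expression(abc_a: float, abc_b: float, rounding: str = "presentation") -> float:
    """Expression fold between two ABC values.

    With the default presentation rounding, folds are first taken to one
    decimal and folds ≥ 10 are then reported to the nearest integer,
    matching how such ratios are quoted (so 39.4995 is quoted as 39.5 →
    40); ``rounding="none"`` returns the raw quotient.
    """
    if abc_a <= 0 or abc_b <= 0:
        raise ValueError("ABC values must be positive")
    fold = abc_a / abc_b
    if rounding == "none":
        return fold
    if rounding == "presentation":
        one_decimal = round(fold, 1)
        return float(round(one_decimal)) if one_decimal >= 10 else one_decimal
    raise ValueError(f"unknown rounding policy {rounding!r}")


def analyze_flow(beads: pd.DataFrame, samples: pd.DataFrame) -> dict:
    """Bead-calibrated analysis of a stained-sample table.

    ``beads`` columns: bead_id, abc, mfi. ``samples`` columns: sample,
    stain ("specific"|"isotype"), mfi, timepoint_h. Reports the
    calibration, per-sample ABC estimates of the specific stains,
    semi-quantitative labels where an isotype partner exists, and fold
    change of ABC versus timepoint 0.
    """
    for col in ("abc", "mfi"):
        if col not in beads.columns:
            raise ValueError(f"beads table lacks column {col!r}")
    cal = fit_bead_calibration([BeadPoint(row.abc, row.mfi) for row in beads.itertuples()])

    required = {"sample", "stain", "mfi", "timepoint_h"}
    if required - set(samples.columns):
        raise ValueError(f"samples table lacks columns {sorted(required - set(samples.columns))}")

    iso = samples[samples.stain == "isotype"].set_index(["sample", "timepoint_h"])
    records = []
    for row in samples[samples.stain == "specific"].itertuples():
        entry = {
            "sample": row.sample,
            "timepoint_h": row.timepoint_h,
            "mfi": row.mfi,
            "abc": abc_from_mfi(row.mfi, cal),
        }
        key = (row.sample, row.timepoint_h)
        if key in iso.index:
            score = semiquant_score(row.mfi, float(iso.loc[key, "mfi"]))
            entry["semiquant"] = score.label
            entry["mfi_ratio"] = score.ratio
        records.append(entry)

    folds = []
    by_sample: dict[str, dict[float, float]] = {}
    for entry in records:
        by_sample.setdefault(entry["sample"], {})[entry["timepoint_h"]] = entry["abc"]
    for sample, series in by_sample.items():
        if 0 in series:
            for tp, abc in sorted(series.items()):
                if tp != 0:
                    folds.append(
                        {
                            "sample": sample,
                            "timepoint_h": tp,
                            "fold_vs_0h": fold_expression(abc, series[0]),
                        }
                    )

    return {"calibration": cal.to_dict(), "samples": records, "fold_changes": folds}
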