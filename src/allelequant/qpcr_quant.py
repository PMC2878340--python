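"""Absolute qPCR quantification with plasmid standard curves.

The measurement model: threshold cycle is linear in the log of starting
template, CT = intercept + slope·log10(copies), with slope < 0. A
standard curve fitted to serial dilutions of a plasmid carrying the
amplicon converts CT of unknowns to absolute copy numbers; the per-cycle
amplification efficiency follows Pfaffl, E = 10^(−1/slope) (E = 2 is
perfect doubling, i.e. slope −3.3219). Copy numbers of a target allele
are divided by those of a reference gene measured in the same sample,
ratios from independent experiments are combined as a geometric mean,
and induction kinetics are expressed as fold change relative to the
unstimulated (t = 0) sample.

Efficiency QC defaults mirror validated assay practice: a hard floor of
1.92 with a warning band below 1.96.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AVOGADRO",
    "DilutionPoint",
    "StandardCurve",
    "conc_to_copies",
    "fit_standard_curve",
    "efficiency_pfaffl",
    "copies_from_ct",
    "normalized_ratio",
    "gmean",
    "fold_change",
    "analyze_qpcr_wells",
]

AVOGADRO = 6.022e23
_G_PER_MOL_BP = 650.0  # average molar mass of a double-stranded base pair

EFFICIENCY_FLOOR = 1.92
EFFICIENCY_WARN = 1.96


@dataclass(frozen=True)
class DilutionPoint:
    """One standard well: plasmid amount and the CT it produced."""

    concentration: float  # ng/µL
    copies: float
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.copies <= 0 or self.ct <= 0:
            raise ValueError("dilution point requires positive concentration, copies and CT")


def conc_to_copies(conc_ng_ul: float, volume_ul: float, plasmid_bp: float) -> float:
    """Plasmid copies delivered to a reaction.

    copies = mass · N_A / (plasmid_size · 650 g/mol per bp), with mass in
    grams from ng/µL × µL.
    """
    if conc_ng_ul <= 0 or volume_ul <= 0 or plasmid_bp <= 0:
        raise ValueError("concentration, volume and plasmid size must be positive")
    grams = conc_ng_ul * volume_ul * 1e-9
    return grams * AVOGADRO / (plasmid_bp * _G_PER_MOL_BP)


def efficiency_pfaffl(slope: float) -> float:
    """Per-cycle amplification efficiency from a standard-curve slope."""
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted CT-vs-log10(copies) line with Pfaffl efficiency and QC.

    Acts as the results object of :func:`fit_standard_curve`: carries the
    estimates, their standard errors, r² and the efficiency QC verdict.
    """

    slope: float
    intercept: float
    r2: float
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        return efficiency_pfaffl(self.slope)

    @property
    def qc(self) -> str:
        e = self.efficiency
        if e < EFFICIENCY_FLOOR or e > 2.1:
            return "fail"
        if e < EFFICIENCY_WARN:
            return "warn"
        return "pass"

    def summary(self) -> str:
        lines = [
            "Standard curve: CT = intercept + slope * log10(copies)",
            f"  n points     {self.n_points}",
            f"  slope        {self.slope:.4f} (se {self.slope_se:.4f}) cycles/log10",
            f"  intercept    {self.intercept:.3f} (se {self.intercept_se:.3f}) cycles",
            f"  r^2          {self.r2:.5f}",
            f"  efficiency E {self.efficiency:.4f} per cycle  [QC: {self.qc}]",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "efficiency": self.efficiency,
            "qc": self.qc,
            "n_points": self.n_points,
        }


def fit_standard_curve(points: Sequence[DilutionPoint]) -> StandardCurve:
    """Ordinary least squares of CT on log10(copies) over a dilution series."""
    if len({round(math.log10(p.copies), 9) for p in points}) < 4:
        raise ValueError("a standard curve needs at least 4 distinct dilution levels")
    x = np.log10([p.copies for p in points])
    y = np.array([p.ct for p in points])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(copies)")
    fit = stats.linregress(x, y)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        n_points=len(points),
    )


def copies_from_ct(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10^((CT − intercept)/slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def normalized_ratio(target_copies: float, reference_copies: float) -> float:
    """Target copy number divided by the reference-gene copy number."""
    if target_copies <= 0 or reference_copies <= 0:
        raise ValueError("copy numbers must be positive")
    return target_copies / reference_copies


def gmean(values: Sequence[float]) -> float:
    """Geometric mean; the paper-standard combiner for ratios across experiments."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of no values")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(stats.gmean(arr))


def fold_change(ratio_t: float, ratio_0: float) -> float:
    """Induction fold at time t relative to the unstimulated baseline."""
    if ratio_t <= 0 or ratio_0 <= 0:
        raise ValueError("ratios must be positive")
    return ratio_t / ratio_0


def analyze_qpcr_wells(
    wells: pd.DataFrame,
    plasmid_bp: float,
    volume_ul: float = 5.0,
    reference: str = "FBXL12",
) -> dict:
    """Full absolute-quantification analysis of a wells table.

    Expected columns: run_id, target, sample, timepoint_h, ct, replicate,
    role ("standard"|"unknown"), conc_ng_ul (standards only). Per run and
    target a standard curve is fitted from the standard wells; technical
    replicates of unknowns are averaged on the CT scale before
    quantification; ratios to the reference gene are formed per sample
    and timepoint, combined across runs by geometric mean, and folds are
    reported relative to timepoint 0.
    """
    required = {"run_id", "target", "sample", "timepoint_h", "ct", "replicate", "role"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table lacks columns {sorted(missing)}")

    curves: dict[tuple, StandardCurve] = {}
    for (run, target), grp in wells[wells.role == "standard"].groupby(["run_id", "target"]):
        points = [
            DilutionPoint(
                concentration=row.conc_ng_ul,
                copies=conc_to_copies(row.conc_ng_ul, volume_ul, plasmid_bp),
                ct=row.ct,
                replicate=row.replicate,
            )
            for row in grp.itertuples()
        ]
        curves[(run, target)] = fit_standard_curve(points)

    unknowns = wells[wells.role == "unknown"]
    quant = (
        unknowns.groupby(["run_id", "target", "sample", "timepoint_h"])["ct"]
        .mean()
        .reset_index()
    )
    quant["copies"] = [
        copies_from_ct(row.ct, curves[(row.run_id, row.target)]) for row in quant.itertuples()
    ]

    ratios = []
    ref_rows = quant[quant.target == reference].set_index(["run_id", "sample", "timepoint_h"])
    for row in quant[quant.target != reference].itertuples():
        key = (row.run_id, row.sample, row.timepoint_h)
        if key not in ref_rows.index:
            continue
        ratios.append(
            {
                "run_id": row.run_id,
                "target": row.target,
                "sample": row.sample,
                "timepoint_h": row.timepoint_h,
                "ratio": normalized_ratio(row.copies, float(ref_rows.loc[key, "copies"])),
            }
        )
    ratio_df = pd.DataFrame(ratios)

    summary = []
    if not ratio_df.empty:
        for (target, sample, tp), grp in ratio_df.groupby(["target", "sample", "timepoint_h"]):
            summary.append(
                {
                    "target": target,
                    "sample": sample,
                    "timepoint_h": tp,
                    "gmean_ratio": gmean(grp.ratio.tolist()),
                    "n_experiments": len(grp),
                }
            )
    summary_df = pd.DataFrame(summary)

    folds = []
    if not summary_df.empty:
        base = summary_df[summary_df.timepoint_h == 0].set_index(["target", "sample"])
        for row in summary_df.itertuples():
            key = (row.target, row.sample)
            if key in base.index and row.timepoint_h != 0:
                folds.append(
                    {
                        "target": row.target,
                        "sample": row.sample,
                        "timepoint_h": row.timepoint_h,
                        "fold_vs_0h": fold_change(
                            row.gmean_ratio, float(base.loc[key, "gmean_ratio"])
                        ),
                    }
                )

    return {
        "curves": {f"{run}:{target}": c.to_dict() for (run, target), c in curves.items()},
        "ratios": ratio_df.to_dict(orient="records"),
        "gmean_ratios": summary_df.to_dict(orient="records"),
        "fold_changes": folds,
        "reference": reference,
    }
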