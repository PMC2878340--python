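"""Complement-dependent microcytotoxicity (CDC) scoring.

Wells are read as counts of dead (red, ethidium-bromide positive) and
live (green, acridine-orange) cells. The kill rate of a serum is the
unweighted mean percent-dead over replicate wells and experiments; a
serum types positive when the mean strictly exceeds the 50 % criterion.
Wells with fewer than 200 counted cells are flagged but not excluded.
The negative-control background (human AB serum, typically ~9 %) is
reported alongside and, by default, NOT subtracted before calling —
the raw >50 % criterion is the standard — with subtraction available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["CdcWell", "CdcResult", "percent_dead", "aggregate_and_call", "analyze_cdc"]

MIN_CELLS = 200
DEFAULT_THRESHOLD = 50.0


@dataclass(frozen=True)
class CdcWell:
    red: int  # dead
    green: int  # live
    serum_id: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.red < 0 or self.green < 0:
            raise ValueError("cell counts cannot be negative")
        if self.red + self.green == 0:
            raise ValueError("empty well: no cells counted")

    @property
    def n_cells(self) -> int:
        return self.red + self.green


@dataclass(frozen=True)
class CdcResult:
    percent_dead: float
    n_cells: int
    call: str  # "positive" | "negative"
    flag_low_count: bool
    n_wells: int = 1
    background_percent: float | None = None


def percent_dead(red: int, green: int) -> float:
    """Cytotoxicity rate of one well: 100·red/(red+green)."""
    if red < 0 or green < 0:
        raise ValueError("cell counts cannot be negative")
    if red + green == 0:
        raise ValueError("empty well: no cells counted")
    return 100.0 * red / (red + green)


def aggregate_and_call(
    wells: Sequence[CdcWell],
    threshold: float = DEFAULT_THRESHOLD,
    background_percent: float | None = None,
    subtract_background: bool = False,
) -> CdcResult:
    """Mean kill rate over wells and the positive/negative typing call.

    The mean is unweighted across wells; the call is positive only when
    it STRICTLY exceeds the threshold (a well-averaged 50.0 % types
    negative). ``flag_low_count`` is set when any well counted fewer
    than 200 cells.
    """
    if not wells:
        raise ValueError("at least one well is required")
    rates = [percent_dead(w.red, w.green) for w in wells]
    mean_rate = sum(rates) / len(rates)
    effective = mean_rate
    if subtract_background:
        if background_percent is None:
            raise ValueError("background subtraction requested without a background value")
        effective = max(mean_rate - background_percent, 0.0)
    return CdcResult(
        percent_dead=mean_rate,
        n_cells=sum(w.n_cells for w in wells),
        call="positive" if effective > threshold else "negative",
        flag_low_count=any(w.n_cells < MIN_CELLS for w in wells),
        n_wells=len(wells),
        background_percent=background_percent,
    )


def analyze_cdc(
    wells: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    background_serum: str = "AB",
    subtract_background: bool = False,
) -> dict:
    """Score a CDC well table per serum.

    Columns: sample, serum_id, replicate, red, green. Rows whose
    serum_id equals ``background_serum`` define the negative-control
    background per sample; it is reported with every call.
    """
    required = {"sample", "serum_id", "replicate", "red", "green"}
    if required - set(wells.columns):
        raise ValueError(f"CDC table lacks columns {sorted(required - set(wells.columns))}")

    results: dict[str, dict] = {}
    for sample, sample_grp in wells.groupby("sample"):
        bg_rows = sample_grp[sample_grp.serum_id == background_serum]
        background = (
            sum(percent_dead(r.red, r.green) for r in bg_rows.itertuples()) / len(bg_rows)
            if len(bg_rows)
            else None
        )
        per_serum = {}
        for serum, grp in sample_grp.groupby("serum_id"):
            if serum == background_serum:
                continue
            ws = [
                CdcWell(red=int(r.red), green=int(r.green), serum_id=serum, replicate=int(r.replicate))
                for r in grp.itertuples()
            ]
            res = aggregate_and_call(
                ws,
                threshold=threshold,
                background_percent=background,
                subtract_background=subtract_background,
            )
            per_serum[serum] = {
                "percent_dead": res.percent_dead,
                "call": res.call,
                "n_wells": res.n_wells,
                "n_cells": res.n_cells,
                "flag_low_count": res.flag_low_count,
            }
        results[sample] = {"background_percent": background, "sera": per_serum}
    return results
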