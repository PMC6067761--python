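"""The nested rulebook turning per-cell break evidence into estimate tiers.

Rural depopulation is counted through three nested cell sets:

* **upper** — the basic direction rule only: mean N rose across the turning
  point (NR_b < NR_a);
* **medium** — additionally, the Mann-Whitney difference is significant
  (two-sided p < alpha, default 0.05);
* **lower** — additionally, the turning point is no later than New Year's
  Day (Julian day 39, inclusive) and the cell contains at least one rural
  settlement site.

Urban cells are handled by the mirrored single rule: a significant
*decrease* (NU_b > NU_a, p < alpha) flags urban decline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .changepoint import TurningPointResult

CNY_DAY = 39  # Julian day of Chinese New Year's Day, 2016 (Feb 8)


@dataclass
class TierAssignment:
    """Nested lower/medium/upper membership for one rural cell."""

    cell_id: str
    in_upper: bool
    in_medium: bool
    in_lower: bool
    settlement_count: int

    def __post_init__(self) -> None:
        # nesting is structural: lower => medium => upper
        assert not (self.in_lower and not self.in_medium)
        assert not (self.in_medium and not self.in_upper)


def assign_tier(
    result: TurningPointResult,
    settlement_count: int,
    cny_day: int = CNY_DAY,
    alpha: float = 0.05,
) -> TierAssignment:
    """Apply the nested criteria to one rural cell's turning-point result."""
    if result.no_break or result.tp_day is None:
        return TierAssignment(result.cell_id, False, False, False, settlement_count)
    upper = result.mean_before < result.mean_after
    medium = upper and result.p_value < alpha
    lower = medium and result.tp_day <= cny_day and settlement_count >= 1
    return TierAssignment(result.cell_id, upper, medium, lower, settlement_count)


def flag_urban_decline(result: TurningPointResult, alpha: float = 0.05) -> bool:
    """True iff the urban cell's mean N significantly decreased across TP."""
    if result.no_break:
        return False
    return result.mean_before > result.mean_after and result.p_value < alpha


def assign_tiers(
    results: Iterable[TurningPointResult] | pd.DataFrame,
    settlement_counts: Mapping[str, int],
    cny_day: int = CNY_DAY,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Batch tier assignment over rural cells.

    ``results`` is either TurningPointResult objects or the breakpoints
    DataFrame from :func:`ruralflux.changepoint.analyze_cells`.
    """
    if isinstance(results, pd.DataFrame):
        results = [
            TurningPointResult(
                cell_id=r.cell_id,
                tp_day=None if pd.isna(r.tp_day) else int(r.tp_day),
                t_min=r.t_min,
                mean_before=r.mean_before,
                mean_after=r.mean_after,
                u_stat=r.u_stat,
                p_value=r.p_value,
                no_break=bool(r.no_break),
            )
            for r in results.itertuples(index=False)
        ]
    rows = []
    for res in results:
        count = int(settlement_counts.get(res.cell_id, 0)) if settlement_counts else 0
        a = assign_tier(res, count, cny_day=cny_day, alpha=alpha)
        rows.append((a.cell_id, a.in_lower, a.in_medium, a.in_upper, a.settlement_count))
    return pd.DataFrame(
        rows, columns=["cell_id", "in_lower", "in_medium", "in_upper", "settlement_count"]
    )


def summarize_tiers(
    assignments: pd.DataFrame, total_settlement_sites: int | None = None
) -> dict:
    """Per-tier cell counts, settlement totals and settlement coverage.

    Coverage is each tier's summed settlement sites over the total rural
    settlement sites — by default those of the assessed (filter-retained)
    cells; pass ``total_settlement_sites`` to use the unfiltered universe.
    """
    if assignments.empty:
        base = 0 if total_settlement_sites is None else int(total_settlement_sites)
        return {
            tier: {"cells": 0, "settlement_sites": 0, "settlement_share": float("nan") if base == 0 else 0.0}
            for tier in ("lower", "medium", "upper")
        }
    total = (
        int(assignments["settlement_count"].sum())
        if total_settlement_sites is None
        else int(total_settlement_sites)
    )
    out = {}
    for tier in ("lower", "medium", "upper"):
        mask = assignments[f"in_{tier}"].astype(bool)
        sites = int(assignments.loc[mask, "settlement_count"].sum())
        out[tier] = {
            "cells": int(mask.sum()),
            "settlement_sites": sites,
            "settlement_share": sites / total if total else float("nan"),
        }
    return out
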