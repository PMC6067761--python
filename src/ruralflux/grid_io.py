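"""Reading, writing and filtering of gridded daily count data.

The central container is :class:`CellSeries`: one grid cell's daily
location-request totals *N* over the observation window, indexed by 1-based
Julian day-of-year. Files are long-format CSV with one row per cell-day
(columns ``cell_id,row,col,julian_day,N``); absent days stay absent — they
are never imputed.

Cells are axis-aligned half-open unit squares: a point with coordinates
(x, y) belongs to column ``floor(x - x0)`` and row ``floor(y - y0)``, so a
point on a cell's lower-left corner is inside it and a point on the grid's
outer maximum edge is outside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GridIntegrityError, GridParseError

GRID_COLUMNS = ["cell_id", "row", "col", "julian_day", "N"]


def cell_id_for(row: int, col: int) -> str:
    """Canonical cell identifier for grid position (row, col)."""
    return f"r{row}c{col}"


@dataclass
class CellSeries:
    """One grid cell's identity, position and daily count series."""

    cell_id: str
    row: int
    col: int
    days: np.ndarray  # strictly increasing Julian day-of-year integers
    counts: np.ndarray  # daily totals N, non-negative integers

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.days.shape != self.counts.shape or self.days.ndim != 1:
            raise GridIntegrityError(
                f"cell {self.cell_id}: days and counts must be 1-D and equal length"
            )
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise GridIntegrityError(
                f"cell {self.cell_id}: days must be strictly increasing"
            )
        if np.any(self.counts < 0):
            raise GridIntegrityError(f"cell {self.cell_id}: negative counts")

    def __len__(self) -> int:
        return int(self.days.size)

    def mean(self) -> float:
        """Arithmetic mean of N over observed days only."""
        return float(self.counts.mean())


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GridParseError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce")
    bad = out.isna() & df[column].notna() | df[column].isna()
    if bad.any():
        # +2: 1 for the header row, 1 for 0- vs 1-based line numbers
        line = int(bad.idxmax()) + 2
        raise GridParseError(f"{path}: malformed value in column {column!r} at line {line}")
    return out


def read_grid(path) -> list[CellSeries]:
    """Read a long-format grid CSV into per-cell series.

    Raises :class:`GridParseError` on malformed rows (naming the line) and
    :class:`GridIntegrityError` on duplicate (cell_id, julian_day) pairs.
    """
    df = pd.read_csv(path)
    _require_columns(df, GRID_COLUMNS, path)
    for col in ("row", "col", "julian_day", "N"):
        df[col] = _numeric(df, col, path).astype(np.int64)
    dup = df.duplicated(subset=["cell_id", "julian_day"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise GridIntegrityError(
            f"{path}: duplicate (cell_id, julian_day) = "
            f"({first['cell_id']}, {first['julian_day']})"
        )
    cells = []
    for cell_id, grp in df.sort_values(["cell_id", "julian_day"]).groupby(
        "cell_id", sort=True
    ):
        cells.append(
            CellSeries(
                cell_id=str(cell_id),
                row=int(grp["row"].iloc[0]),
                col=int(grp["col"].iloc[0]),
                days=grp["julian_day"].to_numpy(),
                counts=grp["N"].to_numpy(),
            )
        )
    return cells


def write_grid(cells: Iterable[CellSeries], path) -> None:
    """Write cells to the long-format CSV (one row per cell-day)."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": c.cell_id,
                "row": c.row,
                "col": c.col,
                "julian_day": c.days,
                "N": c.counts,
            }
        )
        for c in cells
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=GRID_COLUMNS)
    )
    df.to_csv(path, index=False)


def filter_low_activity(
    cells: Sequence[CellSeries], min_mean: float = 2.0
) -> tuple[list[CellSeries], int]:
    """Apply the activity filter: drop cells whose mean daily N is < min_mean.

    The criterion is a strict ``<``: a cell whose mean is exactly ``min_mean``
    is retained. Returns (retained cells, number excluded).
    """
    retained = [c for c in cells if len(c) and c.mean() >= min_mean]
    return retained, len(cells) - len(retained)


@dataclass
class SettlementIndex:
    """Per-cell counts of rural settlement points plus out-of-grid spill."""

    counts: dict[str, int] = field(default_factory=dict)
    n_unassigned: int = 0

    def count(self, cell_id: str) -> int:
        return self.counts.get(cell_id, 0)

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total_sites(self) -> int:
        return self.n_assigned + self.n_unassigned


def index_settlements(
    points: pd.DataFrame,
    n_rows: int,
    n_cols: int,
    origin: tuple[float, float] = (0.0, 0.0),
    cell_size: float = 1.0,
) -> SettlementIndex:
    """Assign settlement points to grid cells by half-open containment.

    ``points`` needs ``x`` and ``y`` columns in the grid's planar frame.
    A point on the lower/left edge of a cell belongs to it; a point on the
    grid's outer maximum edge (or anywhere outside) is counted as unassigned.
    """
    _require_columns(points, ["x", "y"], "settlements")
    x0, y0 = origin
    col = np.floor((points["x"].to_numpy(float) - x0) / cell_size).astype(np.int64)
    row = np.floor((points["y"].to_numpy(float) - y0) / cell_size).astype(np.int64)
    inside = (row >= 0) & (row < n_rows) & (col >= 0) & (col < n_cols)
    index = SettlementIndex(n_unassigned=int((~inside).sum()))
    ids = [cell_id_for(r, c) for r, c in zip(row[inside], col[inside])]
    for cid in ids:
        index.counts[cid] = index.counts.get(cid, 0) + 1
    return index


def read_settlements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "x", "y"], path)
    return df


def write_settlements(points: pd.DataFrame, path) -> None:
    points.to_csv(path, index=False)


def read_radiance(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "radiance"], path)
    return df


def read_region_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "county_id", "city_id", "province_id"], path)
    return df


def write_ascii_raster(
    values: Mapping[str, float],
    cells: Sequence[CellSeries],
    n_rows: int,
    n_cols: int,
    path,
    nodata: float = -9999.0,
    origin: tuple[float, float] = (0.0, 0.0),
    cell_size: float = 1.0,
) -> None:
    """Export a per-cell scalar as a single-band Esri ASCII grid (.asc).

    Cells absent from ``values`` get the nodata value. Row 0 is the grid's
    southernmost row, so it is written last (ASCII grids are north-up).
    """
    grid = np.full((n_rows, n_cols), nodata, dtype=float)
    for c in cells:
        if c.cell_id in values:
            grid[c.row, c.col] = values[c.cell_id]
    header = (
        f"ncols {n_cols}\nnrows {n_rows}\n"
        f"xllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell_size}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for r in range(n_rows - 1, -1, -1):
            fh.write(" ".join(format(v, ".6g") for v in grid[r]) + "\n")


def write_data_dictionary(path) -> None:
    """Write the column dictionary for every file format this package emits."""
    text = """# Data dictionary

## grid.csv (long format, one row per cell-day)
- cell_id: opaque cell identifier (string, 'r{row}c{col}')
- row, col: 0-based grid indices
- julian_day: 1-based day-of-year (Jan 16 2016 = 16 ... Feb 13 2016 = 44)
- N: daily location-request total for the cell (non-negative integer)

## radiance.csv
- cell_id; radiance: nighttime-light radiance, 1e-9 W cm-2 sr-1 (>= 0)

## settlements.csv
- id: settlement point id; x, y: planar coordinates in grid units

## region_map.csv
- cell_id; county_id; city_id; province_id (every cell in exactly one county)

## census.csv (county level)
- county_id; city_id; province_id
- registered_pop: persons registered (hukou) in the county
- resident_hukou_pop: persons with local hukou still resident
- agri_share: resident agricultural population share (0..1)
- nonhukou_ratio: inhabitants without local hukou / with local hukou

## truth_cells.csv (synthetic ground truth)
- cell_id; true_domain: urban|rural|empty
- true_break_day: implanted break day (Julian) or empty if none
- true_effect: multiplicative step factor (1 = no step)

## truth_regions.csv (synthetic ground truth)
- county_id; true_out_migrants: implanted out-migrants (persons)

## breakpoints.csv
- cell_id; tp_day: detected turning point (first day of the post-break
  regime); t_min: minimized unit-root t-statistic; mean_before, mean_after:
  average N before/after TP; u_stat, p_value: Mann-Whitney U and two-sided p;
  no_break: 1 if the series was degenerate (no detectable break)

## tiers.csv
- cell_id; in_lower, in_medium, in_upper: nested estimate membership;
  settlement_count; (urban cells are in urban_decline.csv instead)
"""
    Path(path).write_text(text)
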