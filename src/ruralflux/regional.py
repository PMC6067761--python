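"""Regional and country-level aggregation of per-cell break results.

Per cell, the net change in daily location requests is NR_a - NR_b (counts
per day) and the relative rate is that net over NR_b. Regions (counties,
merged into cities and provinces) aggregate the positive nets of their
qualifying rural cells into a regional net increase, and the prevalence PR
is the share of a region's rural cells whose N increased. Country-level
daily sums per domain (urban / rural / other) give the festival's share
dynamics; the return fraction converts the rural-share peak against its
pre-festival baseline into the fraction of the usually-urban population that
returned to the countryside. Census-side operations select counting-eligible
counties, infer out-migrants from hukou accounting, and regress regional net
increases on out-migrants for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st

from .errors import GridIntegrityError
from .grid_io import CellSeries

REGION_LEVELS = ("county", "city", "province")


# ---------------------------------------------------------------------------
# per-cell quantities

def cell_net_increase(result) -> float:
    """Net change NR_a - NR_b in daily counts (positive = increase)."""
    return float(result.mean_after - result.mean_before)


def cell_relative_rate(result) -> float:
    """Relative rate (NR_a - NR_b) / NR_b; nan when NR_b is 0."""
    if result.mean_before == 0:
        return float("nan")
    return cell_net_increase(result) / float(result.mean_before)


# ---------------------------------------------------------------------------
# regional aggregation

def _level_column(level: str) -> str:
    if level not in REGION_LEVELS:
        raise ValueError(f"unknown level {level!r}")
    return f"{level}_id"


def aggregate_regions(
    results: pd.DataFrame,
    region_map: pd.DataFrame,
    labels: pd.Series,
    level: str = "county",
    tier_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-region net increase/decrease and prevalence at one level.

    ``results`` is the breakpoints table (cell_id, mean_before, mean_after,
    ...), ``labels`` the urban/rural partition labels indexed by cell_id and
    ``region_map`` the cell-to-county/city/province table. ``tier_mask``
    (boolean, indexed by cell_id) optionally restricts which increased rural
    cells count toward the net increase (e.g. medium-tier membership);
    without it every rural cell with net > 0 qualifies.

    Output columns: region_id, n_rural, n_urban, net_increase (sum of
    positive rural nets), net_decrease (sum of urban declines, positive
    number), pr (share of rural cells with net > 0), rural_share and
    urban_share (the region's fraction of the two grand totals).
    """
    col = _level_column(level)
    df = results.merge(region_map, on="cell_id", how="left", validate="one_to_one")
    if df[col].isna().any():
        missing = df.loc[df[col].isna(), "cell_id"].iloc[0]
        raise GridIntegrityError(f"cell {missing!r} is not mapped to a {level}")
    df["label"] = df["cell_id"].map(labels)
    df["net"] = df["mean_after"] - df["mean_before"]

    rural = df[df["label"] == "rural"].copy()
    urban = df[df["label"] == "urban"].copy()
    qualify = rural["net"] > 0
    if tier_mask is not None:
        qualify &= rural["cell_id"].map(tier_mask).fillna(False).astype(bool)

    rows = []
    for region, grp in df.groupby(col, sort=True):
        r = rural[rural[col] == region]
        u = urban[urban[col] == region]
        rq = qualify.loc[r.index]
        net_inc = float(r.loc[rq, "net"].sum())
        net_dec = float(-u.loc[u["net"] < 0, "net"].sum())
        pr = float((r["net"] > 0).mean()) if len(r) else float("nan")
        rows.append((region, len(r), len(u), net_inc, net_dec, pr))
    out = pd.DataFrame(
        rows,
        columns=["region_id", "n_rural", "n_urban", "net_increase", "net_decrease", "pr"],
    )
    total_inc = out["net_increase"].sum()
    total_dec = out["net_decrease"].sum()
    out["rural_share"] = out["net_increase"] / total_inc if total_inc > 0 else np.nan
    out["urban_share"] = out["net_decrease"] / total_dec if total_dec > 0 else np.nan
    out["level"] = level
    return out


# ---------------------------------------------------------------------------
# country-level time series

def country_series(cells: list[CellSeries], labels: pd.Series) -> pd.DataFrame:
    """Daily nationwide sum of N per domain (urban / rural / other).

    Cells without a partition label (e.g. dropped by the activity filter)
    form the 'other' domain. Returns a day-indexed DataFrame with one column
    per domain plus 'total'.
    """
    sums: dict[str, dict[int, float]] = {}
    for cell in cells:
        domain = labels.get(cell.cell_id, "other") if len(labels) else "other"
        bucket = sums.setdefault(domain, {})
        for day, n in zip(cell.days, cell.counts):
            bucket[int(day)] = bucket.get(int(day), 0.0) + float(n)
    df = pd.DataFrame(sums).sort_index()
    df.index.name = "julian_day"
    df = df.fillna(0.0)
    df["total"] = df.sum(axis=1)
    return df


def domain_proportions(daily_sums: pd.DataFrame) -> pd.DataFrame:
    """Daily share of each domain in the country total.

    Days with a zero total get nan shares and are flagged in the
    ``undefined`` column. Shares sum to 1 on every defined day.
    """
    total = daily_sums["total"]
    domains = [c for c in daily_sums.columns if c != "total"]
    shares = daily_sums[domains].div(total.where(total > 0), axis=0)
    shares["undefined"] = total <= 0
    return shares


def rural_share_peak(shares: pd.DataFrame) -> tuple[int, float]:
    """(peak day, peak share) of the rural domain's daily share."""
    rural = shares["rural"].dropna()
    day = int(rural.idxmax())
    return day, float(rural.loc[day])


def urban_return_fraction(p_peak: float, p_base: float) -> float:
    """Fraction of the usually-urban population that returned to the
    countryside, from the rural share at its festival peak against its
    pre-festival baseline: (p_peak - p_base) / (1 - p_base)."""
    if not 0 <= p_base < 1:
        raise ValueError("p_base must be in [0, 1)")
    if p_peak < p_base:
        raise ValueError("p_peak must be >= p_base")
    return (p_peak - p_base) / (1.0 - p_base)


def kendall_tau(series) -> tuple[float, float]:
    """Kendall's tau-b trend of a series against time (asymptotic p).

    Constant series have an undefined tau; (nan, nan) is returned.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = _st.kendalltau(np.arange(y.size), y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def zscore(series) -> np.ndarray:
    """Standard score (mean 0, sample SD 1)."""
    y = np.asarray(series, dtype=float)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series has no standard score")
    return (y - y.mean()) / sd


# ---------------------------------------------------------------------------
# regressions

@dataclass
class FitResult:
    """OLS fit summary for the regional regressions."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided p of the slope
    slope_ci: tuple[float, float]  # 95% confidence interval of the slope
    n_used: int
    n_dropped: int


def _ols(x: np.ndarray, y: np.ndarray, n_dropped: int) -> FitResult:
    if x.size < 3:
        raise ValueError("need at least 3 usable pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: no variation in x")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return FitResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n_used=int(x.size),
        n_dropped=n_dropped,
    )


def fit_loglog(x, y) -> FitResult:
    """OLS of ln y on ln x; non-positive pairs dropped (count reported)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    return _ols(np.log(x[keep]), np.log(y[keep]), int((~keep).sum()))


def fit_log(x, y) -> FitResult:
    """OLS of y on ln x (y = a + b ln x); non-positive x dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x > 0) & np.isfinite(x) & np.isfinite(y)
    return _ols(np.log(x[keep]), y[keep], int((~keep).sum()))


def fit_linear(x, y) -> FitResult:
    """Plain OLS of y on x (used for the census validation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return _ols(x[keep], y[keep], int((~keep).sum()))


# ---------------------------------------------------------------------------
# source / sink classification

def classify_source_sink(rural_share: float, urban_share: float, k: float = 2.0) -> str:
    """Label a region source, sink or balanced by its share imbalance.

    With y = rural_share and x = urban_share, the deviation lines are
    y = (k+1)x and x = (k+1)y (k = 2 by default, i.e. y = 2x + x): a region
    is a *source* when its rural-increase share exceeds (k+1) times its
    urban-decrease share, a *sink* in the mirrored case, else *balanced*.
    """
    if rural_share < 0 or urban_share < 0:
        raise ValueError("shares must be >= 0")
    y, x = rural_share, urban_share
    if y > (k + 1) * x:
        return "source"
    if x > (k + 1) * y:
        return "sink"
    return "balanced"


# ---------------------------------------------------------------------------
# census operations

def select_counties(census: pd.DataFrame) -> pd.DataFrame:
    """Counties eligible for out-migrant accounting.

    Keeps counties whose resident agricultural population share exceeds 50%
    (drops urbanized areas) and whose ratio of non-hukou to hukou inhabitants
    is below 0.10 (drops areas with notable in-migration). Both strict.
    """
    for col in ("agri_share", "nonhukou_ratio"):
        if col not in census.columns:
            raise ValueError(f"census table missing column {col!r}")
    mask = (census["agri_share"] > 0.5) & (census["nonhukou_ratio"] < 0.10)
    return census[mask].copy()


def infer_out_migrants(registered: float, resident_hukou: float) -> float:
    """Out-migrants = registered population - hukou population still resident.

    A negative value (more hukou holders resident than registered) indicates
    net inflow and is returned as-is; callers flag it.
    """
    if registered < 0 or resident_hukou < 0:
        raise ValueError("populations must be >= 0")
    return float(registered) - float(resident_hukou)


def out_migrant_table(census: pd.DataFrame) -> pd.DataFrame:
    """Vectorised hukou accounting with a net-inflow flag per county."""
    out = census.copy()
    out["out_migrants"] = out["registered_pop"].astype(float) - out[
        "resident_hukou_pop"
    ].astype(float)
    out["net_inflow"] = out["out_migrants"] < 0
    return out


def validate_against_census(
    region_summaries: pd.DataFrame, out_migrants: pd.Series
) -> FitResult:
    """OLS of regional net increase on census-inferred out-migrants.

    ``region_summaries`` is the output of :func:`aggregate_regions` for one
    level; ``out_migrants`` is indexed by region_id. Returns the linear fit
    (slope, R^2, p) whose positive, significant slope validates the
    location-request proxy against the census.
    """
    x = region_summaries["region_id"].map(out_migrants).to_numpy(dtype=float)
    y = region_summaries["net_increase"].to_numpy(dtype=float)
    return fit_linear(x, y)
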