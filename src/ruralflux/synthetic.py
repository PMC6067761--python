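"""Synthetic study-condition generator with recorded ground truth.

Emulates the statistical structure the pipeline assumes of its (proprietary)
inputs: per-cell daily location-request counts are Poisson with a
piecewise-constant mean that steps at an implanted break day near Chinese
New Year — up (factor > 1) in affected rural cells, down (factor < 1) in
urban cells, constant in the rest; "empty" cells run below the activity
filter. Nightlight radiances are drawn per land class from normals with the
published class statistics, censored at zero. Rural settlement points are
scattered Poisson-many per rural cell. County tables implement hukou
accounting: registered minus resident-hukou population equals the implanted
out-migrants, which are proportionally coupled to the county's implanted
rural effect mass.

Everything derives from a single master seed through spawned substreams, so
an identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .grid_io import CellSeries, cell_id_for
from .nightlight import LARGE_CITY, RURAL, SMALL_CITY, ClassStats


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the published setting: a 29-day window (Julian days
    16..44 of 2016) around New Year's Day (day 39); rural cells outnumber
    urban roughly as in the retained nationwide grid; rural baseline counts
    are low (5/day) and step up threefold in the ~60% of rural cells that
    hold an implanted effect, while urban cells step down; empty cells run
    below the mean-2 activity filter.
    """

    n_rows: int = 25
    n_cols: int = 40
    day_start: int = 16
    day_end: int = 44  # inclusive
    cny_day: int = 39
    n_urban: int = 260
    n_rural: int = 640
    n_empty: int = 100
    baseline_urban: float = 50.0
    baseline_rural: float = 5.0
    baseline_empty: float = 1.0
    effect_urban: float = 0.4
    effect_rural: float = 3.0
    frac_affected_rural: float = 0.6
    break_day_jitter: int = 3
    nightlight_stats: tuple[ClassStats, ClassStats, ClassStats] = (
        LARGE_CITY,
        SMALL_CITY,
        RURAL,
    )
    settlements_per_rural_cell: float = 1.1
    n_provinces: int = 5
    n_cities: int = 10
    n_counties: int = 20
    persons_per_unit_net: float = 100.0
    seed: int = 0

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.day_start, self.day_end + 1)

    @property
    def n_cells(self) -> int:
        return self.n_urban + self.n_rural + self.n_empty

    def validate(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.n_cells == 0:
            raise ConfigurationError("grid must be non-empty")
        if self.n_cells != self.n_rows * self.n_cols:
            raise ConfigurationError(
                f"class counts ({self.n_cells}) must fill the "
                f"{self.n_rows}x{self.n_cols} grid exactly"
            )
        for name in ("baseline_urban", "baseline_rural", "baseline_empty",
                     "effect_urban", "effect_rural", "settlements_per_rural_cell",
                     "persons_per_unit_net"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not 0 <= self.frac_affected_rural <= 1:
            raise ConfigurationError("frac_affected_rural must be in [0, 1]")
        if not self.day_start <= self.cny_day <= self.day_end:
            raise ConfigurationError("day_range must cover cny_day")
        if self.break_day_jitter < 0:
            raise ConfigurationError("break_day_jitter must be >= 0")
        if not self.n_counties >= self.n_cities >= self.n_provinces >= 1:
            raise ConfigurationError("need n_counties >= n_cities >= n_provinces >= 1")


@dataclass
class SyntheticTruth:
    """Generator ground truth for recovery tests.

    ``cells``: cell_id, row, col, true_domain, true_break_day (nan when no
    step), true_effect. ``regions``: per county — implanted out-migrants and
    the census-side population fields. ``region_map``: cell-to-region table.
    """

    cells: pd.DataFrame
    regions: pd.DataFrame
    region_map: pd.DataFrame


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus the generating truth."""

    cells: list[CellSeries]
    radiance: pd.DataFrame  # cell_id, radiance
    settlements: pd.DataFrame  # id, x, y
    region_map: pd.DataFrame  # cell_id, county_id, city_id, province_id
    truth: SyntheticTruth
    config: GeneratorConfig = field(repr=False, default=None)


def _draw_radiance(rng: np.random.Generator, stats: ClassStats, size: int) -> np.ndarray:
    # censored (not resampled) at zero: keeps every draw, atom at 0
    return np.maximum(rng.normal(stats.mean, stats.sd, size), 0.0)


def generate_grid(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset for one configuration."""
    config.validate()
    large_stats, small_stats, rural_stats = config.nightlight_stats
    ss = np.random.SeedSequence(config.seed)
    (s_assign, s_counts, s_rad, s_settle, s_regions) = ss.spawn(5)
    rng_assign = np.random.default_rng(s_assign)
    rng_counts = np.random.default_rng(s_counts)
    rng_rad = np.random.default_rng(s_rad)
    rng_settle = np.random.default_rng(s_settle)
    rng_regions = np.random.default_rng(s_regions)

    n = config.n_cells
    days = config.days

    # spatial class assignment: classes scattered uniformly over the grid
    positions = np.arange(n)
    rng_assign.shuffle(positions)  # positions[i] = flat grid slot of cell i
    domains = np.array(
        ["urban"] * config.n_urban + ["rural"] * config.n_rural + ["empty"] * config.n_empty
    )
    rows = positions // config.n_cols
    cols = positions % config.n_cols
    ids = np.array([cell_id_for(r, c) for r, c in zip(rows, cols)])

    # implanted effects
    effects = np.ones(n)
    break_days = np.full(n, np.nan)
    lo, hi = config.cny_day - config.break_day_jitter, config.cny_day + config.break_day_jitter
    rural_idx = np.flatnonzero(domains == "rural")
    n_affected = int(round(config.frac_affected_rural * config.n_rural))
    affected = rng_assign.choice(rural_idx, size=n_affected, replace=False)
    effects[affected] = config.effect_rural
    break_days[affected] = rng_assign.integers(lo, hi + 1, size=n_affected)
    urban_idx = np.flatnonzero(domains == "urban")
    effects[urban_idx] = config.effect_urban
    break_days[urban_idx] = rng_assign.integers(lo, hi + 1, size=urban_idx.size)

    baselines = np.select(
        [domains == "urban", domains == "rural"],
        [config.baseline_urban, config.baseline_rural],
        default=config.baseline_empty,
    )

    cells: list[CellSeries] = []
    for i in range(n):
        mean = np.full(days.size, baselines[i])
        if np.isfinite(break_days[i]):
            mean[days >= break_days[i]] = baselines[i] * effects[i]
        counts = rng_counts.poisson(mean)
        cells.append(CellSeries(ids[i], int(rows[i]), int(cols[i]), days.copy(), counts))

    # radiance: urban cells split evenly between the two city classes
    radiance = np.empty(n)
    city_class = rng_rad.random(urban_idx.size) < 0.5
    radiance[urban_idx[city_class]] = _draw_radiance(
        rng_rad, large_stats, int(city_class.sum())
    )
    radiance[urban_idx[~city_class]] = _draw_radiance(
        rng_rad, small_stats, int((~city_class).sum())
    )
    non_urban = np.flatnonzero(domains != "urban")
    radiance[non_urban] = _draw_radiance(rng_rad, rural_stats, non_urban.size)
    radiance_df = pd.DataFrame({"cell_id": ids, "radiance": radiance})

    # settlements: Poisson-many points uniform inside each rural cell
    pts = []
    for i in rural_idx:
        k = rng_settle.poisson(config.settlements_per_rural_cell)
        for _ in range(k):
            pts.append(
                (cols[i] + rng_settle.random(), rows[i] + rng_settle.random())
            )
    settlements = pd.DataFrame(pts, columns=["x", "y"])
    settlements.insert(0, "id", [f"s{j:06d}" for j in range(len(settlements))])

    # region membership: contiguous row-major bands of counties
    order = np.argsort(positions)  # cells sorted by flat grid slot
    county = np.empty(n, dtype=int)
    county[order] = np.arange(n) * config.n_counties // n
    city = county * config.n_cities // config.n_counties
    province = county * config.n_provinces // config.n_counties
    region_map = pd.DataFrame(
        {
            "cell_id": ids,
            "county_id": [f"county{c:03d}" for c in county],
            "city_id": [f"city{c:03d}" for c in city],
            "province_id": [f"prov{c:03d}" for c in province],
        }
    )

    # county truth: out-migrants coupled to the implanted rural effect mass
    daily_net = np.zeros(n)
    daily_net[affected] = config.baseline_rural * (config.effect_rural - 1.0)
    county_net = pd.Series(daily_net).groupby(county).sum()
    region_rows = []
    for c in range(config.n_counties):
        mass = float(county_net.get(c, 0.0))
        out_migrants = int(round(config.persons_per_unit_net * mass))
        resident = int(rng_regions.integers(50_000, 200_000))
        if rng_regions.random() < 0.8:  # counting-eligible county
            agri = float(rng_regions.uniform(0.55, 0.95))
            ratio = float(rng_regions.uniform(0.0, 0.09))
        elif rng_regions.random() < 0.5:
            agri = float(rng_regions.uniform(0.2, 0.5))
            ratio = float(rng_regions.uniform(0.0, 0.09))
        else:
            agri = float(rng_regions.uniform(0.55, 0.95))
            ratio = float(rng_regions.uniform(0.10, 0.30))
        region_rows.append(
            (
                f"county{c:03d}",
                f"city{c * config.n_cities // config.n_counties:03d}",
                f"prov{c * config.n_provinces // config.n_counties:03d}",
                out_migrants,
                resident + out_migrants,
                resident,
                agri,
                ratio,
            )
        )
    regions = pd.DataFrame(
        region_rows,
        columns=[
            "county_id",
            "city_id",
            "province_id",
            "true_out_migrants",
            "registered_pop",
            "resident_hukou_pop",
            "agri_share",
            "nonhukou_ratio",
        ],
    )

    truth_cells = pd.DataFrame(
        {
            "cell_id": ids,
            "row": rows,
            "col": cols,
            "true_domain": domains,
            "true_break_day": break_days,
            "true_effect": effects,
        }
    )
    truth = SyntheticTruth(cells=truth_cells, regions=regions, region_map=region_map)
    return SyntheticDataset(
        cells=cells,
        radiance=radiance_df,
        settlements=settlements,
        region_map=region_map,
        truth=truth,
        config=config,
    )


def generate_census(
    truth: SyntheticTruth, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Observed county census table from the truth, with optional noise.

    The registered-minus-resident difference equals the implanted
    out-migrants up to multiplicative noise of relative SD ``noise_sd``
    (exact at ``noise_sd=0``).
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if truth.regions.empty:
        raise ConfigurationError("truth contains no region records")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out = truth.regions[
        [
            "county_id",
            "city_id",
            "province_id",
            "resident_hukou_pop",
            "agri_share",
            "nonhukou_ratio",
        ]
    ].copy()
    migrants = truth.regions["true_out_migrants"].to_numpy(dtype=float)
    if noise_sd > 0:
        migrants = np.round(migrants * (1.0 + rng.normal(0.0, noise_sd, migrants.size)))
        migrants = np.maximum(migrants, 0.0)
    out["registered_pop"] = out["resident_hukou_pop"] + migrants.astype(int)
    return out[
        [
            "county_id",
            "city_id",
            "province_id",
            "registered_pop",
            "resident_hukou_pop",
            "agri_share",
            "nonhukou_ratio",
        ]
    ]


def generate_visitor_series(
    length: int = 62,
    coupling: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired daily (visitors, N) series; N is a noisy affine map of visitors.

    The default 62-day window matches the park comparison the standard-score
    check emulates. ``coupling`` scales how strongly N follows the visitor
    signal (0 decouples them); ``noise_sd`` is the noise SD relative to the
    transformed signal's SD.
    """
    if length < 3:
        raise ConfigurationError("length must be >= 3")
    rng = np.random.default_rng(seed)
    t = np.arange(length)
    visitors = (
        800.0
        + 400.0 * np.sin(2 * np.pi * t / 21.0)
        + rng.normal(0.0, 60.0, length)
    )
    visitors = np.maximum(visitors, 0.0)
    slope, intercept = 2.0, 100.0
    signal_sd = slope * visitors.std(ddof=1)
    n = intercept + coupling * slope * visitors + rng.normal(
        0.0, noise_sd * signal_sd, length
    )
    return pd.DataFrame({"day": t + 1, "visitors": visitors, "N": n})


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A fast ~1,000-cell demo configuration (29 days)."""
    return replace(GeneratorConfig(seed=seed), **overrides)
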