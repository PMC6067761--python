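"""Regional aggregation, country series, regressions, census operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import pearsonr

from ruralflux.changepoint import TurningPointResult
from ruralflux.errors import GridIntegrityError
from ruralflux.regional import (
    aggregate_regions,
    cell_net_increase,
    cell_relative_rate,
    classify_source_sink,
    country_series,
    domain_proportions,
    fit_linear,
    fit_log,
    fit_loglog,
    infer_out_migrants,
    kendall_tau,
    out_migrant_table,
    rural_share_peak,
    select_counties,
    urban_return_fraction,
    validate_against_census,
    zscore,
)
from ruralflux.synthetic import generate_visitor_series


def _result(mb, ma):
    return TurningPointResult("c", 38, -3.0, mb, ma, 1.0, 0.01)


class TestCellQuantities:
    def test_net_and_rate(self):
        r = _result(2, 5)
        assert cell_net_increase(r) == 3
        assert cell_relative_rate(r) == 1.5

    def test_no_change(self):
        r = _result(4, 4)
        assert cell_net_increase(r) == 0 and cell_relative_rate(r) == 0

    def test_zero_baseline_rate_is_missing(self):
        r = _result(0, 5)
        assert cell_net_increase(r) == 5
        assert np.isnan(cell_relative_rate(r))


def _toy_tables():
    results = pd.DataFrame(
        {
            "cell_id": ["a", "b", "c", "d", "e"],
            "mean_before": [2.0, 3.0, 5.0, 10.0, 4.0],
            "mean_after": [5.0, 5.0, 4.0, 6.0, 9.0],
        }
    )
    region_map = pd.DataFrame(
        {
            "cell_id": ["a", "b", "c", "d", "e"],
            "county_id": ["c1", "c1", "c1", "c2", "c2"],
            "city_id": ["m1", "m1", "m1", "m1", "m1"],
            "province_id": ["p1", "p1", "p1", "p1", "p1"],
        }
    )
    labels = pd.Series(
        ["rural", "rural", "rural", "urban", "rural"],
        index=["a", "b", "c", "d", "e"],
    )
    return results, region_map, labels


class TestAggregateRegions:
    def test_net_increase_sums_qualifying_cells(self):
        results, region_map, labels = _toy_tables()
        out = aggregate_regions(results, region_map, labels, level="county")
        c1 = out.set_index("region_id").loc["c1"]
        assert c1["net_increase"] == pytest.approx(3 + 2)  # a:+3, b:+2; c declines
        assert c1["pr"] == pytest.approx(2 / 3)
        c2 = out.set_index("region_id").loc["c2"]
        assert c2["net_decrease"] == pytest.approx(4)  # urban cell d: 10 -> 6

    def test_merged_level_is_additive(self):
        results, region_map, labels = _toy_tables()
        county = aggregate_regions(results, region_map, labels, level="county")
        province = aggregate_regions(results, region_map, labels, level="province")
        assert province["net_increase"].iloc[0] == pytest.approx(
            county["net_increase"].sum()
        )
        assert province["net_decrease"].iloc[0] == pytest.approx(
            county["net_decrease"].sum()
        )

    def test_shares_sum_to_one(self):
        results, region_map, labels = _toy_tables()
        out = aggregate_regions(results, region_map, labels, level="county")
        assert out["rural_share"].sum() == pytest.approx(1.0)
        assert out["urban_share"].sum() == pytest.approx(1.0)

    def test_unmapped_cell_is_integrity_error(self):
        results, region_map, labels = _toy_tables()
        with pytest.raises(GridIntegrityError):
            aggregate_regions(results, region_map.iloc[:-1], labels, level="county")


class TestCountrySeries:
    def test_domain_shares(self, demo_dataset):
        from ruralflux.nightlight import classify_cells

        labels = classify_cells(demo_dataset.radiance).labels
        daily = country_series(demo_dataset.cells, labels)
        shares = domain_proportions(daily)
        domains = [c for c in shares.columns if c != "undefined"]
        sums = shares[domains].sum(axis=1)
        assert np.allclose(sums[~shares["undefined"]], 1.0, atol=1e-12)

    def test_share_arithmetic(self):
        daily = pd.DataFrame(
            {"rural": [398.0], "urban": [500.0], "other": [102.0]}, index=[39]
        )
        daily["total"] = daily.sum(axis=1)
        shares = domain_proportions(daily)
        assert shares.loc[39, "rural"] == pytest.approx(0.398)

    def test_all_zero_day_is_flagged(self):
        daily = pd.DataFrame({"rural": [0.0], "urban": [0.0]}, index=[20])
        daily["total"] = 0.0
        shares = domain_proportions(daily)
        assert bool(shares.loc[20, "undefined"])
        assert np.isnan(shares.loc[20, "rural"])

    def test_rural_share_peaks_after_breaks_start(self, demo_dataset):
        """With permanent implanted steps the rural share cannot peak before
        the first implanted break day."""
        from ruralflux.nightlight import classify_cells

        cfg = demo_dataset.config
        labels = classify_cells(demo_dataset.radiance).labels
        shares = domain_proportions(country_series(demo_dataset.cells, labels))
        day, share = rural_share_peak(shares)
        assert day >= cfg.cny_day - cfg.break_day_jitter
        assert share > shares.loc[shares.index < cfg.cny_day - 15, "rural"].mean()


class TestReturnFraction:
    def test_published_inputs(self):
        assert urban_return_fraction(0.398, 0.184) == pytest.approx(0.262, abs=5e-4)

    def test_degenerate_cases(self):
        assert urban_return_fraction(0.3, 0.3) == 0.0
        assert urban_return_fraction(1.0, 0.5) == 1.0

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            urban_return_fraction(1.2, 1.0)


def kendall_oracle(y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    y = np.asarray(y, float)
    n = y.size
    conc = disc = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = y[j] - y[i]
            if d > 0:
                conc += 1
            elif d < 0:
                disc += 1
            else:
                ties_y += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt(n0 * (n0 - ties_y))


class TestKendall:
    def test_monotone_series(self):
        assert kendall_tau(np.arange(10))[0] == pytest.approx(1.0)
        assert kendall_tau(np.arange(10)[::-1])[0] == pytest.approx(-1.0)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            y = rng.integers(0, 8, 29)
            if np.ptp(y) == 0:
                continue
            tau, p = kendall_tau(y)
            assert tau == pytest.approx(kendall_oracle(y), abs=1e-12)
            assert 0 < p <= 1

    def test_constant_series_flagged(self):
        tau, p = kendall_tau([3, 3, 3, 3])
        assert np.isnan(tau) and np.isnan(p)


class TestFits:
    def test_loglog_exact_recovery(self):
        x = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
        y = np.exp(1.0 + 2.0 * np.log(x))
        fit = fit_loglog(x, y)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_loglog_slope_recovery_within_ci(self, rng):
        x = rng.lognormal(10, 1, 50)
        y = np.exp(0.5 + 1.3 * np.log(x) + rng.normal(0, 0.4, 50))
        fit = fit_loglog(x, y)
        assert fit.slope_ci[0] < 1.3 < fit.slope_ci[1]

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_loglog([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            fit_loglog([1.0, 2.0], [1.0, 2.0])

    def test_log_fit_exact_and_drops_nonpositive(self):
        x = np.array([1.0, 3.0, 7.0, 20.0, -2.0, 0.0])
        y = 0.1 + 0.2 * np.log(np.where(x > 0, x, 1.0))
        fit = fit_log(x, y)
        assert fit.intercept == pytest.approx(0.1)
        assert fit.slope == pytest.approx(0.2)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_dropped == 2 and fit.n_used == 4


class TestSourceSink:
    @pytest.mark.parametrize(
        "rural,urban,expected",
        [(0.06, 0.01, "source"), (0.01, 0.06, "sink"), (0.02, 0.02, "balanced")],
    )
    def test_deviation_rule(self, rural, urban, expected):
        assert classify_source_sink(rural, urban) == expected

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_swap_maps_source_to_sink(self, a, b):
        first = classify_source_sink(a, b)
        second = classify_source_sink(b, a)
        assert {first, second} in ({"balanced"}, {"source", "sink"}) or (
            first == second == "balanced"
        )


class TestCensusOps:
    def test_selection_rules(self):
        census = pd.DataFrame(
            {
                "county_id": ["a", "b", "c"],
                "agri_share": [0.6, 0.4, 0.6],
                "nonhukou_ratio": [0.05, 0.05, 0.10],
            }
        )
        kept = select_counties(census)
        assert list(kept["county_id"]) == ["a"]  # b fails agri, c fails ratio (strict)

    def test_out_migrant_difference(self):
        assert infer_out_migrants(100_000, 80_000) == 20_000
        assert infer_out_migrants(5, 5) == 0
        assert infer_out_migrants(80_000, 100_000) == -20_000

    def test_inflow_flag(self):
        t = out_migrant_table(
            pd.DataFrame(
                {"registered_pop": [100, 80], "resident_hukou_pop": [80, 100]}
            )
        )
        assert list(t["net_inflow"]) == [False, True]

    def test_perfectly_proportional_validation(self):
        regions = pd.DataFrame(
            {"region_id": ["a", "b", "c", "d"], "net_increase": [10.0, 20.0, 30.0, 40.0]}
        )
        migrants = pd.Series([1000.0, 2000.0, 3000.0, 4000.0], index=list("abcd"))
        fit = validate_against_census(regions, migrants)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.01)

    def test_coupled_validation_recovers_positive_slope(self, rng):
        migrants = pd.Series(rng.uniform(1e4, 1e5, 30), index=[f"c{i}" for i in range(30)])
        net = 0.002 * migrants * (1 + rng.normal(0, 0.1, 30))
        regions = pd.DataFrame({"region_id": migrants.index, "net_increase": net.values})
        fit = validate_against_census(regions, migrants)
        assert fit.slope > 0 and fit.p_value < 0.05

    def test_uncoupled_validation_slope_is_null(self, rng):
        """With out-migrants independent of the net increase the slope
        t-statistic behaves like a null: |t| < 2 in >= 90% of replicates."""
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.uniform(1e4, 1e5, 30)
            y = rng.normal(50, 10, 30)
            fit = fit_linear(x, y)
            se = (fit.slope_ci[1] - fit.slope_ci[0]) / (2 * 2.048)  # t_{0.975,28}
            hits += abs(fit.slope / se) < 2
        assert hits / reps >= 0.9


class TestZscore:
    def test_standardizes(self):
        z = zscore([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        y = rng.normal(5, 2, 40)
        np.testing.assert_allclose(zscore(y), zscore(3.0 * y + 7.0), atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0])

    def test_coupled_visitor_series_correlates_after_standardization(self):
        df = generate_visitor_series(coupling=1.0, noise_sd=0.1, seed=42)
        r, _ = pearsonr(zscore(df["visitors"]), zscore(df["N"]))
        assert r > 0.9
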