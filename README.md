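# ruralflux

Grid cell-level estimation of rural depopulation from daily gridded
location-request counts around Chinese New Year.

During *Chunyun* — the New Year travel season — most rural out-migrants
return from the cities to their home villages. A grid of daily
location-request totals *N* (one ~1 km cell per row-day) therefore shows a
step **up** in rural cells and a step **down** in urban cells around New
Year's Day. `ruralflux` turns that natural experiment into per-cell and
regional estimates of the prevalence and magnitude of rural depopulation.
It is aimed at researchers in human mobility and population dynamics who
want the full analysis chain as tested, reusable code, exercised end-to-end
on a synthetic-data generator with recorded ground truth.

## Method

For each grid cell with average *N* ≥ 2 over the 29-day window (Julian days
16–44 of 2016; New Year's Day = day 39):

1. **Urban/rural partition** from nighttime-light radiance. In one
   dimension the Mahalanobis distance is |x − μ|/σ; with class statistics
   *rural villages* 0.377 ± 0.27 and *small cities* 11.71 ± 7.97
   (10⁻⁹ W cm⁻² sr⁻¹), cells at or below the radiance threshold 0.738 are
   rural, the rest urban (`derive_threshold` exposes the equal-distance
   construction, which gives ≈ 0.7483).
2. **Turning point (TP)** per cell by a Zivot–Andrews-style minimum-t
   search: for every candidate break day *b* in the trimmed interior, fit

   Δy_t = μ + θ·1[t ≥ b] + β·t + α·y_{t−1} + e_t

   and take the *b* minimizing the t-statistic of α. TP is the first day of
   the post-break regime.
3. **Confirmation** of the level shift by a two-sided Mann–Whitney U test
   between the sub-series before (day < TP) and after (day ≥ TP), with
   exact permutation p-values at small n and a tie/continuity-corrected
   normal approximation otherwise.
4. **Nested estimate tiers** for rural cells — upper: NR_b < NR_a;
   medium: + p < 0.05; lower: + TP ≤ 39 and ≥ 1 rural settlement site in
   the cell. Urban cells with significantly decreased N are flagged as
   urban decline.
5. **Regional statistics**: net increase Σ(NR_a − NR_b), prevalence PR
   (share of rural cells with increased N), country-level domain shares,
   the urban return fraction (p_peak − p_base)/(1 − p_base), Kendall-tau
   trends, log–log and semi-log regressions, source/sink labels from the
   y = (k+1)x deviation lines (k = 2), and validation against
   census-style hukou accounting (out-migrants = registered − resident
   hukou population, over counties with agricultural share > 50% and
   non-hukou ratio < 0.10).

## Worked example

```bash
ruralflux demo --outdir demo_run --seed 1
```

runs the whole chain on a generated 1,000-cell, 29-day dataset and prints
the manifest; `demo_run/summary.json` then holds the headline numbers:

```
"counts": {
  "cells_total": 1000, "cells_retained": 900, "cells_excluded": 100,
  "urban": 299, "rural": 601, "settlement_sites": 699,
  "tier_lower": 144, "tier_medium": 344, "tier_upper": 465,
  "urban_decline": 236
}
rural_share_peak_day: 44        rural_share_peak: 0.549
rural_share_baseline: 0.217     urban_return_fraction: 0.423
```

Reading: of 1,000 generated cells, 100 fell below the activity filter;
nightlights split the rest into 299 urban and 601 rural cells. 465 rural
cells had increased N (upper estimate), 344 of them significant (medium),
and 144 also broke before New Year's Day in a cell containing a settlement
(lower). The rural share of the country-level daily total rises from a
pre-festival baseline of 21.7% to a 54.9% peak; because the generator
implants permanent steps, the peak sits at the window's end rather than
on New Year's Day itself. Stage outputs (partition, per-cell breakpoints,
tier table, per-level regional summaries, regression fits) are plain CSV
and JSON files in the run directory; the same stages are callable
individually (`ruralflux generate|filter|partition|detect|tiers|run-all`)
or from Python (`ruralflux.run_pipeline`).

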