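# heatmatch

Matched heatwave-exposure analysis for daily health-outcome counts at the
ZCTA (Zip Code Tabulation Area) level.

Epidemiological studies of heatwaves and emergency-department (ED) visits
often pair each heatwave day with non-heatwave "control" days from the same
location and estimate relative risks within matched strata. `heatmatch`
implements that full design as a reusable pipeline, aimed at environmental-
health researchers working with daily weather series and daily outcome
counts (e.g. maternal mental-health ED visits during warm seasons):

1. **Heatwave detection** with the Excess Heat Factor (EHF). For each day
   *i*, with T̄₃(i) the 3-day mean temperature ending on day *i* and T95 the
   location's 95th-percentile daily mean temperature,

       EHI_sig(i)  = T̄₃(i) − T95
       EHI_accl(i) = T̄₃(i) − mean of the preceding 30 days
       EHF(i)      = EHI_sig(i) × max(1, EHI_accl(i))      [°C²]

   A day is a heatwave day iff EHF > 0; tiers are low (0 < EHF < 1),
   moderate (1 ≤ EHF < 2) and high (EHF ≥ 2). Two alternative definitions —
   runs of ≥ 3 consecutive days above the location's 95th-percentile daily
   mean temperature or NWS heat index — are provided for sensitivity work.
2. **Matched control-day sampling**: each heatwave day is matched with 3
   randomly selected non-heatwave days from the same ZCTA, within a window
   of 2 days before to 7 days after the case's season-day, in a *different*
   year, and at least 3 days away from any heatwave day.
3. **Conditional quasi-Poisson estimation** with distributed lags: Poisson
   regression of daily counts with one intercept per ZCTA profiled out
   ("eliminated"), a log-population offset, day-of-week and year adjustment,
   and indicator terms for heatwave exposure at lags 0–7. Cumulative acute
   (lag 0–3) and prolonged (lag 0–7) relative risks are delta-method sums of
   lag coefficients; standard errors are inflated by the Pearson dispersion.
4. **Effect modification** across subgroups (age band, race, ethnicity,
   insurance, rurality, region, neighborhood ICE quintiles) via the Wald
   heterogeneity statistic W = (β₁ − β₂)² / (SE₁² + SE₂²) ~ χ²(1).
5. **Neighborhood context**: Index of Concentration at the Extremes
   (ICE = (advantaged − disadvantaged) / total, in [−1, 1]) for racialized
   and economic polarization, rank-based quintiles, and RUCA
   rural/suburban/urban classes.
6. **Synthetic data generation** with known ground truth (seasonal weather
   with injected heat episodes, overdispersed counts whose log-rate matches
   the fitted model), so every stage is testable without restricted data.

## Worked example

```python
import numpy as np
import heatmatch as hm

cfg = hm.SyntheticConfig(
    n_zcta=50, years=(2011, 2012, 2013),
    true_log_rr_by_lag={l: np.log(1.5) / 4 for l in range(4)},
    seed=7,
)
weather = hm.generate_weather(cfg)
calendar = hm.compute_ehf(weather)
n_events = int(calendar.groupby("zcta")["event_id"].max().sum())
print("heatwave days:", int(calendar["is_heatwave"].sum()), "| events:", n_events)

counts, truth = hm.generate_counts(cfg, calendar, weather)
sets, drops = hm.match_controls(calendar, hm.MatchConfig(seed=8))
print("matched sets:", sets["set_id"].nunique(), "| dropped cases:", len(drops))

table = hm.build_matched_table(sets, counts, calendar, lag_max=3)
fit = hm.fit_conditional_quasipoisson(table, lags=(0, 1, 2, 3))
print(hm.cumulative_rr(fit, hm.LagSpec.acute()).round(4).to_string(index=False))
print(f"dispersion: {fit.dispersion:.3f}")
```

prints

```
heatwave days: 823 | events: 248
matched sets: 823 | dropped cases: 0
             term   beta     se     rr  ci_low  ci_high      p
cumulative_lag0-3 0.2173 0.1194 1.2427  0.9834   1.5704 0.0688
dispersion: 0.988
```

Here the generator injected a true cumulative acute relative risk of 1.5
(log 1.5 split evenly over lags 0–3). The fitted cumulative RR of 1.24 with
95 % CI (0.98, 1.57) covers the truth: at 50 ZCTAs × 3 seasons a single
replicate is noisy, and the calibration studies below quantify coverage and
bias at larger sizes. The dispersion near 1 reflects the equidispersed
default generator.

A `heatmatch` console script exposes the same stages for shell use
(`heatmatch generate`, `exposure`, `match`, `fit`, `stratify`, `describe`,
`run`, `report`); `heatmatch run --config run.yaml --out outdir/` executes
the whole pipeline and writes every intermediate CSV plus a reproducibility
manifest.

## Layout

- `src/heatmatch/synthetic.py` — ground-truth data generator
- `src/heatmatch/exposure.py` — EHF / percentile heatwave calendars, heat index
- `src/heatmatch/matching.py` — control-day eligibility, sampling, lagged table
- `src/heatmatch/model.py` — conditional quasi-Poisson, cumulative RRs
- `src/heatmatch/stratify.py` — subgroup fits, W heterogeneity statistic
- `src/heatmatch/context.py` — ICE, quintiles, RUCA classes
- `src/heatmatch/describe.py` — summary tables, chi-square tests
- `src/heatmatch/calibration.py` — simulation studies of the full pipeline
- `src/heatmatch/pipeline.py`, `cli.py` — orchestration and console script
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
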