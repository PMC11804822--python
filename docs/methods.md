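# Methods

This note records the models the package implements, the assumptions and
numerical choices behind them, and what the synthetic-data studies do and do
not demonstrate.

## Heatwave detection

**Excess Heat Factor (EHF).** Daily mean temperature series are scored per
ZCTA within each season-year block (default warm season May–September).
With T̄₃(i) the `mean_window_days` (default 3) mean and T95 the per-ZCTA
`percentile` (default 0.95) quantile of all in-season daily means over the
study period:

- EHI_sig(i) = T̄₃(i) − T95 — excess over the local climatological threshold;
- EHI_accl(i) = T̄₃(i) − mean of the `accl_window_days` (default 30) days
  immediately preceding the 3-day window — short-term acclimatization;
- EHF(i) = EHI_sig(i) × max(1, EHI_accl(i)), in °C². The clamp means
  acclimatization can only amplify, never rescue, a sub-threshold day, so a
  heatwave day (EHF > 0) always has EHI_sig > 0.

Intensity tiers partition the positive axis: low (0, 1), moderate [1, 2),
high [2, ∞). The boundary at 2 is closed on the high side so the printed
open intervals become an exhaustive partition.

*Window alignment.* The 3-day mean is **trailing** by default (day *i* and
the two prior days) so that exposure is fully determined on the admission
day being modelled; the original EHF literature's forward-looking window is
available via `window_alignment="leading"`. This is a genuine convention
choice; lag indexing of health outcomes motivates the trailing default.

*Season boundaries.* With warm-season-only data there is no cross-winter
continuity, so the first `accl_window + mean_window − 1` (default 32) days
of each season-year cannot be scored. They are flagged `scored=False`,
never heatwave days, and are ineligible as control days (their exposure
status is unverifiable). T95 uses all in-season days of the study period.

*Percentile rule.* Linear interpolation between order statistics
(`numpy.quantile`, method `"linear"`); alternative interpolation rules are
selectable for sensitivity analysis.

**Percentile-run definitions.** The alternative definitions flag maximal
runs of at least `min_run_days` (default 3) consecutive days strictly above
the per-ZCTA 95th percentile of daily mean temperature (`PCTL_TEMP`) or
daily heat index (`PCTL_HI`). These have no intensity tiers.

**Heat index.** Re-implemented from the US National Weather Service
algorithm: the Rothfusz (1990) regression with the published low-humidity
(RH < 13 %, 80–112 °F) and high-humidity (RH > 85 %, 80–87 °F) adjustments,
and the Steadman-average simple formula below the 80 °F switch. Computation
is in °F internally with exact 9/5 conversions; inputs are daily mean
temperature (°C) and relative humidity (%) and the output is °C.

## Matched design

Each heatwave day (case) is matched with up to `n_controls` (default 3)
control days from the same ZCTA satisfying all of:

- **different calendar year** than the case;
- **seasonal window**: control season-day index within [case − 2, case + 7]
  (defaults). The index is anchored at the first day of the season month
  (May 1), which aligns the same seasonal position across years and is
  robust to leap years;
- **non-heatwave** and **scored**;
- **buffer**: no heatwave day within ±`buffer_days` (default 3) calendar
  days. By default the buffer tests against *any* heatwave day (the
  stricter reading — for cross-year controls every nearby event is
  necessarily a different event from the case's); the literal
  "other-event-only" scope is available via `buffer_scope="other_event"`.

Sampling is uniform without replacement within a set from a seeded stream;
the same calendar day may serve as control for different cases. Sets with
fewer than `min_controls` (default 1) candidates are dropped and recorded
in a drop report rather than raising.

The analysis table has one row per set-member day (optionally per subgroup
level) with the outcome count (zero-filled where absent), population,
day-of-week, year, and heatwave indicators at lags 0..L read from the
calendar; rows whose lag look-back leaves the observed calendar are
excluded and counted.

## Conditional quasi-Poisson model

Counts are modelled as Poisson with
log μ = α_{ZCTA} + x'β + log(population), where x holds the lag indicators
and day-of-week / year categories. The per-stratum intercepts are profiled
out: given β each α has a closed form, and the profiled likelihood is the
product-multinomial likelihood of counts given stratum totals. Point
estimates therefore coincide with a Poisson fit carrying explicit stratum
indicator columns (verified to 1e-6 in the tests) at much lower cost.

- **Optimization**: Newton–Raphson on the profiled likelihood with
  step-halving on divergence; convergence when the relative log-likelihood
  change is below 1e-10, at most 100 iterations; non-convergence raises.
- **Stratum** defaults to ZCTA (the elimination term of the published
  design); matched-set conditioning is available via `strata="set_id"`.
  Strata whose outcome total is zero are uninformative under conditioning
  and are dropped with a count.
- **Dispersion**: φ = Pearson X² / (n − p), with p counting slope
  parameters *and* eliminated intercepts. Reported standard errors are
  model SE × √φ; CIs are exp(β ± 1.96·SE) and p-values are two-sided Wald.
- **Offset vs weights**: population enters as a log offset only. Using it
  simultaneously as a prior weight would double-count exposure scale, so
  weighting is not enabled by default.
- **Lag basis**: unconstrained indicator per lag (no spline smoothing).
  Cumulative acute (lags 0–3) and prolonged (0–7) log-RRs are sums of lag
  coefficients with delta-method variance 1'Σ1 over the φ-scaled
  covariance block.
- The plain conditional Poisson variant (φ ≡ 1) shares the estimating
  equations, hence identical point estimates; `compare_model_variants`
  reports both interval widths side by side. Mixed-effects (GLMM) variants
  are out of scope.

## Stratification and effect modification

Separate models are fitted within each level of a subgroup axis. For two
levels with cumulative log-RRs β₁, β₂ and standard errors SE₁, SE₂,
W = (β₁ − β₂)² / (SE₁² + SE₂²) is referred to χ²(1); p < 0.05 flags effect
modification. For axes with more than two levels each level is compared to
a declared reference level by default (all pairs optionally); no
multiple-testing correction is applied by default (a Bonferroni pass can be
layered on the output table). `se_from_ci` recovers the log-scale SE from a
published RR and 95 % CI — (ln hi − ln lo) / 3.92 — so published estimates
can feed the test directly.

## Neighborhood context

ICE = (advantaged − disadvantaged) / total in [−1, 1]. Default components
follow the established convention: racialized ICE uses non-Hispanic White
vs Black residents over total population; economic ICE uses top-quintile
vs bottom-quintile income households over total households. Both are
configurable column mappings. Quintiles are rank-based with minimum-rank
ties: q = ⌈5r/n⌉, so Q1 holds the lowest (most disadvantaged) scores, tied
scores share a quintile, and an all-tied vector collapses to Q1 with a
warning; an inversion flag flips the direction. The rule is invariant to
monotone transformations.

The shipped RUCA collapse maps codes 1–3 → Rural, 4–6 → Suburban,
7–10 → Urban, following the source study as printed. Note this inverts the
usual USDA reading, in which codes 1–3 are metropolitan; that conventional
mapping ships as the named alternative `"usda"`.

## Descriptives

Percentages are n/denominator rounded half-up to one decimal. Two
denominator rules are explicit parameters because published tables mix
them: `all_visits` (total including unknown labels; used for ethnicity,
race, insurance, age) and `known_only` (sum over known labels; used for
rural-urban class and region). The packaged `table1_counts.csv` is a
transcription of a published summary table; transcription was verified
against row and column totals where possible. Known internal
inconsistencies of the printed source are preserved as printed and excluded
from exact checks: the insurance "all visits" column sums to 324,265
(printed total 324,928), the severe-mental-illness insurance column sums to
497 (printed 503), and the printed Medicaid percentage (55.4) disagrees
with its own count (179,627 / 324,928 = 55.3). The summary-table chi-square
is implemented as a goodness-of-fit of each outcome's level counts against
the all-visit proportions — an interpretation, since the published footnote
does not fully specify the comparison.

## Synthetic data

The generator emulates the *structure* of a warm-season multi-year
ZCTA-level surveillance study, not any real climate or population:

- **Temperature**: per (ZCTA, season) a half-sine seasonal curve
  (baseline 24 °C, amplitude 5 °C) plus stationary AR(1) noise (ρ = 0.7,
  SD 1.8 °C) plus injected heat episodes — Poisson(2) episodes per season,
  lengths uniform on 3–6 days, +6 °C — which give EHF something real to
  detect. Humidity is bounded AR(1) around 65 %, present only to exercise
  the heat-index path.
- **Counts**: log-rate = log(pop) + log(baseline rate per 100k, default 1)
  + day-of-week effect + year effect + Σ_l β_l HW(t−l), exactly the fitted
  model's structure, so injected β are a valid recovery target.
  Overdispersion φ > 1 is realized by gamma mixing (negative binomial with
  mean μ and variance φμ), the standard generative stand-in for the
  quasi-Poisson mean-variance law.
- **Subgroups**: independent axes (age band, race, ethnicity, insurance)
  with mixing proportions matching the marginal composition of a large
  southeastern US maternal ED sample; cross-classified cell counts are
  emitted so any axis can be marginalized. Effect modification is injected
  by overriding the lag-β map for cells of a named level.
- Populations are single per-ZCTA scalars (10k–50k uniform); the ACS-style
  ICE component counts are drawn from beta distributions solely to give the
  index arithmetic realistic inputs.

What passing recovery tests show: the pipeline's stages compose correctly
and the estimator is approximately unbiased with near-nominal coverage
*when the data-generating process matches the model*. They do not show
robustness to confounding structures the generator lacks (within-season
outcome trends, spatially correlated exposure misclassification, joint
subgroup structure), nor anything about any specific real dataset.

## Calibration studies and problem sizes

`heatmatch.calibration` runs the full chain per replicate. The shipped
study sizes are: recovery at 200 ZCTAs × 5 seasons with a true cumulative
acute RR of 1.5 (100 replicates in the test suite) — mean log-RR bias is
required to be below 0.02 and 95 % CI coverage at least 90 %; and a null
study at 40 ZCTAs × 3 seasons (500 replicates) — lag-0 Wald type-I error
required to lie in [0.03, 0.07]. The acceptance script reports the same
quantities at 40 and 200 replicates respectively, a size chosen to keep a
single-CPU run in the few-minutes range while leaving Monte-Carlo error
well inside the bands.

Published headline relative risks from the motivating design (built on
restricted hospital discharge records and a proprietary weather feed) are
not reproducible from first principles here; the package's acceptance
surface is exact reproduction of the printed descriptive percentages plus
the parameter-recovery and calibration studies above.

## Known limitations

- The conditional fit assumes within-stratum independence of daily counts;
  serial correlation in residual rates would understate SEs (partially
  absorbed by the quasi-Poisson φ).
- Wald inference only; no likelihood-ratio or small-sample corrections, so
  subgroup fits on very sparse outcomes can be anticonservative.
- The matcher treats unscored (season warm-up) days as ineligible controls,
  which slightly narrows the control pool for early-season cases.
- Leap years are handled by season-day anchoring; series containing
  February are untested territory (the design is warm-season only).
- `effect_modification` compares levels pairwise; global heterogeneity
  tests across >2 levels are not provided.
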