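# Methods

This note documents the models and procedures implemented in `alcpolicy`,
the assumptions they make, the defaults and why, and what the synthetic
generators do and do not emulate.

## Problem setting

Evaluating national alcohol-control policy cannot use randomized designs;
the standard tool is the interrupted time series (ITS), comparing the
observed post-intervention trend of a monthly outcome (per-capita
consumption, alcohol-attributable deaths) with the counterfactual trend
projected from pre-intervention data. Before any such evaluation, each
dated policy event must be classified by its *expected* impact, so that
hypotheses (which dates, which effect shapes) are fixed a priori. The
package implements that classification for the Lithuanian 2000–2019
policy sequence and the surrounding machinery — affordability index,
eligibility rules, cumulative exposure score, expert-rating sensitivity
analysis, and the ITS estimator itself — as reusable, testable parts.

## Affordability index

With an annual disposable-income index `I_y` and an alcohol-price index
`P_y` (both scaled to a base year = 100), the affordability level is
`100·(I_y/P_y)/(I_b/P_b)` and the year-over-year proportional change is

```
change(y) = 100 · ( I_y/P_y − I_{y−1}/P_{y−1} ) / ( I_{y−1}/P_{y−1} )   [percent]
```

Positive changes mean alcohol became more affordable. Changes are banded:
**decrease** (`< 0`), **small increase** (`0 ≤ c < 5%`), **large
increase** (`≥ 5%`); the 5% default is the median affordability change of
the study period. Internals keep full precision; the one-decimal/integer
rounding is display-only, and the banding always compares the unrounded
value (avoids ties manufactured by rounding — no assignment in the
bundled data flips either way).

Recomputing the published one-decimal changes from the published
two-component indices reproduces every year except four (2008: −0.2 vs
−0.1; 2015: 9.2 vs 9.1; 2016: 5.2 vs 5.3; 2018: 5.4 vs 5.3), evidently
because the original table was computed from unrounded source series.
The bundled CSV carries the component indices; the four ±0.1 pp years are
treated as documented discrepancies in the tests. No tier assignment is
sensitive to them.

## Policy timeline

Events are dated bundles of measures typed by domain (taxation/price,
availability, marketing/advertising, drink-driving, other), direction
(restrictive / liberalizing / neutral), population reach (general /
specific group), availability scope (daily hours, specific days or
night, outlet type, production/licensing) and immediacy (immediate /
delayed). These attributes are *curated*, not parsed from legal prose:
the bundled Lithuanian timeline records each curation choice in its
`curation_notes`. One event may bundle several measures enacted on the
same date (the 2008 "Year of Sobriety" package bundles tax, drink-driving
and advertising measures).

## Tier rules

Rule order per event:

1. any liberalizing measure and no qualifying measure → excluded
   (liberalizing policies are left unscored, not negatively scored);
2. all measures target a specific group → `specific` (evaluated against
   group-specific outcomes, never scored);
3. fewer than `min_pre` months strictly before the enactment month, or
   fewer than `min_post` months from the enactment month to the window
   end (inclusive) → excluded, under-powered (defaults 24/24);
4. **Tier 1** if a restrictive general-population tax/price measure
   coincides with an affordability *decrease* in its enactment calendar
   year, or a restrictive general-population availability measure limits
   *daily* sales hours;
5. else **Tier 2** if such a tax measure coincides with a small
   (< threshold) affordability increase, or a restrictive availability
   measure is limited to certain days/night hours;
6. else excluded (no criterion — e.g. a marketing ban alone, whose
   effects accrue too slowly for a step hypothesis).

Affordability attribution uses the enactment *calendar year* because the
economic indices are annual. Mixed bundles are classified by their best
qualifying measure, and `criteria_fired` records every criterion that
held (the 2009 event qualifies on both its tax and its night-sales
measure; which alone would have sufficed is not decidable from the
source material and is deliberately left visible rather than resolved).
Tier-1 criteria nest inside tier-2 criteria, so every tier-1 event is
also tier-2-qualified; `tier2_only` labels the increment.

The cumulative policy score is a right-continuous monthly step function:
each scored event adds its weight (tier 1: 1.0, tier-2-only: 0.5) from
its enactment month onward. On the bundled data the path is
0 → 1 (2008-01) → 1.5 (2009-01) → 2 (2014-04) → 3 (2017-03) → 4 (2018-01).

The observation window start is configurable (default 2000-01). The
June 2001 tax rise has only 17 pre-months in that window and is excluded
on power grounds regardless of where exactly the outcome series begins.

## Expert-rating sensitivity analysis

Experts rate every measure 0–10 for predicted immediate impact
(modified nominal group technique: independent ratings, no meeting).
A date is *selected* when the best mean rating among its measures is
≥ 5 (inclusive). Items are grouped by enactment date because the
timeline organizes measures that way.

Interrater reliability is ICC(2,1) — two-way random effects, absolute
agreement, single rater — computed from the two-way ANOVA mean squares,
with the standard F-based confidence interval (Satterthwaite df). The
variant is the common default for interrater reliability when none is
named; it penalizes systematic rater offsets, which is the relevant
notion when absolute 0–10 levels drive selection. Pairwise Spearman
rank correlations (average ranks on ties) are summarized by median and
IQR; pairs involving a constant rater are undefined, excluded and
flagged. Degenerate (zero-variance) matrices raise rather than return a
conventional value.

The original five experts' ratings were never published, so their
reliability statistics are not reproducible; the implementation is
instead verified against an independent brute-force variance-components
oracle (and against `pingouin`), and the selection/concordance logic
against constructed rating matrices. Missing ratings are disallowed by
default; an opt-in mode averages available raters and flags the matrix
as incomplete.

## ITS estimator

Design matrix: intercept; linear month counter; 11 month-of-year
indicators (December reference); one column per economic covariate; per
intervention a 0/1 step from the enactment month (*abrupt*) or a ramp
rising `1/L, 2/L, …, 1` over `L = lag_months` and staying at 1
(*lagged*: part of the effect immediate, the rest accruing). A rank
check rejects collinear designs (e.g. two interventions in the same
month). Alternatively (or additionally) the cumulative policy score
enters as a single exposure column, estimating an effect per score unit.

Errors are modelled as AR(1) and handled by iterative quasi-differencing
(Cochrane–Orcutt): estimate `rho` by regressing lag-1 residuals,
transform `y*_t = y_t − rho·y_{t−1}` (and each regressor), refit OLS,
iterate until `|Δrho| < 1e−6` (max 50 iterations; non-convergence warns
and returns the last iterate with a flag). AR(1)-only was chosen over
ARIMA order selection as the simplest defensible monthly-data default;
it is switchable off. When residuals are at floating-point level
(near-exact fits) `rho` is pinned to 0 rather than estimated from
numerical noise. Confidence intervals use the t distribution with the
transformed model's residual degrees of freedom; no small-sample
correction beyond that. Quasi-differencing drops one observation's
worth of information but keeps coefficients on the original outcome
scale.

Design checks report pre/post month counts per intervention against the
24/24 minimum and an advisory against the recommended 50–100 total time
points.

## Synthetic data

The generators state a world and keep it fixed:

* **Outcome** (`simulate_outcome`): monthly value = baseline 1.2 (litres
  pure alcohol per capita per month, the scale of a high-consumption
  European country) + trend 0.001/month + 0.1·cos(2π·month/12) + step or
  ramp policy effects + covariate terms + AR(1) noise (rho 0.3,
  innovation SD 0.05, stationary start) over Jan 2000 – Dec 2019
  (240 months). Covariates are standardized AR(1) (0.8) paths. The
  single-cosine seasonal is nested inside the estimator's month
  indicators, so seasonal misspecification is absent by construction —
  a green recovery test certifies estimator correctness under the
  assumed data-generating process, not robustness to real-data features
  (changing seasonal amplitude, outliers, level shifts from emigration,
  measurement revisions).
* **Economy** (`simulate_economy`): income follows a multiplicative
  random walk (drift 4%/yr, SD 2%/yr, plausible for the period); prices
  are solved from the affordability recursion so requested year-over-year
  changes are reproduced exactly (to float precision), then both paths
  are rebased to 100 in the base year.
* **Ratings** (`simulate_ratings`): `clip(round(truth + rater bias +
  noise), 0, 10)` with 5 raters, bias SD 1.0, noise SD 1.5 — chosen to
  produce mid-range agreement of the kind reported for real expert
  panels; agreement falls monotonically as noise grows (verified by
  simulation).

Reproducibility: every stream derives from `SeedSequence(seed,
spawn_key=k)` with fixed per-stream keys, so adding a generator never
shifts existing outputs, and all generators are bit-reproducible for a
fixed seed.

## Numerical and design choices

* Threshold comparisons (affordability banding, rating selection) use
  unrounded values and inclusive lower bounds (`0 ≤ c < 5`; mean ≥ 5).
* First series year has no affordability change (never imputed 0).
* The classification rule order places the specific-population test
  before the window test; the 2019 drink-driving amendment is therefore
  labelled `specific` rather than under-powered (it is both; it is never
  scored either way).
* Score steps take effect in the enactment month itself, matching the
  convention that January 2008 is the first treated month.
* Pipeline runs write a manifest (config hash, seed, version) and refuse
  to overwrite outputs without `force`; identical configs produce
  byte-identical outputs.

## Known limitations

* Availability "major vs minor" is carried by the curated scope
  attribute; the underlying evidence base for ranking availability
  restrictions is thin, so these labels are a modelling convention, not
  a measurement.
* The affordability definition ignores the general consumer price index
  (alternative definitions deflate by CPI); beverage-specific indices
  are out of scope.
* The ITS module fits the design; it does not perform ARIMA order
  search, synthetic-control or difference-in-differences analyses.
* Liberalizing policies are left unscored rather than negatively
  weighted; the 2001–2004 liberalization era therefore contributes
  nothing to the cumulative score.
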