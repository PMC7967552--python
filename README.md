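# alcpolicy

Classify alcohol-control policies into impact tiers and evaluate them
with interrupted time series (ITS) designs.

## Who this is for

Epidemiologists and policy researchers preparing a formal evaluation of
a country's alcohol-control legislation. Before estimating effects, each
dated policy event must be classified *a priori* by its expected impact,
so that the evaluation tests pre-registered hypotheses instead of
post-hoc stories. `alcpolicy` implements that classification for the
Lithuanian 2000–2019 policy sequence — shipped as a curated, editable
dataset — and generalizes every step so it can be re-run on another
country's timeline.

## What it computes

**Affordability.** From annual disposable-income and alcohol-price
indices `I_y`, `P_y` (base year = 100), the affordability index
`100·(I_y/P_y)/(I_b/P_b)` and its year-over-year proportional change

```
change(y) = 100 · ( I_y/P_y − I_{y−1}/P_{y−1} ) / ( I_{y−1}/P_{y−1} )  [%]
```

banded into decrease / small increase (< 5%) / large increase. A tax
rise only counts as an immediate price intervention when affordability
actually fell.

**Tier rules.** Each event becomes `tier1` (tax rise with an
affordability decrease, or a daily sales-hours restriction for the
general population), `tier2_only` (tax rise with a sub-threshold
affordability increase, or day/night-limited availability restriction),
`specific` (targets a specific group; analysed separately, never
scored), or `excluded` (liberalizing, under-powered — fewer than 24
months before or after within the study window — or meeting no
criterion). Scored events sum into a monthly **cumulative policy score**
(tier 1: +1.0, tier-2-only: +0.5), usable as an exposure regressor.

**Expert sensitivity analysis.** 0–10 ratings from an independent
expert panel are aggregated per measure; dates whose best mean rating
is ≥ 5 are selected and compared with the criteria-based selection.
Agreement statistics: ICC(2,1) with an F-based 95% CI, and the
median/IQR of pairwise Spearman correlations.

**ITS estimator.** Segmented regression on monthly data — intercept,
trend, month-of-year seasonality, covariates, and step (abrupt) or ramp
(lagged) terms per intervention — with AR(1) errors handled by iterative
Cochrane–Orcutt quasi-differencing. Design checks enforce the 24/24
pre/post minimum and the 50–100 total-point recommendation.

**Synthetic data.** Generators for economy series hitting requested
affordability changes exactly, outcome series with known policy effects,
and rating matrices with controllable agreement — so the whole pipeline
runs and is testable with no external data.

## Worked example

```python
import alcpolicy as ap

econ = ap.load_lithuania_economy()          # Table of annual indices, 2007-2019
events = ap.load_lithuania_timeline()       # 21 curated policy events
window = ap.StudyWindow.from_strings("2000-01", "2019-12")

assignments = ap.classify(events, econ, window)
for a in assignments:
    if a.tier.value != "excluded":
        print(a.enactment_date, a.tier.value,
              [c.value for c in a.criteria_fired],
              None if a.affordability_change_used is None
              else round(a.affordability_change_used, 1))
score = ap.cumulative_score(assignments, window)
print("final score:", score.value_at("2019-12"))
```

prints

```
2008-01-01 tier1 ['affordability_decrease'] -0.2
2009-01-01 tier2_only ['affordability_small_increase', 'availability_minor'] 3.0
2014-04-01 tier2_only ['affordability_small_increase'] 3.9
2015-01-01 specific ['specific_population'] None
2016-01-01 specific ['specific_population'] None
2017-01-01 specific ['specific_population'] None
2017-03-01 tier1 ['affordability_decrease'] -6.7
2018-01-01 tier1 ['availability_major'] None
2019-04-01 specific ['specific_population'] None
final score: 4.0
```

Reading: three events qualify for tier 1 — the January 2008 tax package
(affordability fell 0.2%), the March 2017 record excise increase
(−6.7%), and the January 2018 availability package (daily sales-hour
limits). Two more qualify only for tier 2 — January 2009 (+3.0%
affordability, plus a night-sales restriction) and April 2014 (+3.9%).
Four drink-driving / petrol-station measures target specific groups.
Everything else is liberalizing, under-powered, or meets no criterion
(e.g. the March 2015 tax rise, swallowed by 9.2% affordability growth).
The cumulative score steps 0 → 1 → 1.5 → 2 → 3 → 4 across those five
dates.

Evaluating a (here: simulated) outcome series against one of the dates:

```python
from alcpolicy import SimulationConfig, SimulatedEffect, simulate_outcome, fit_its

cfg = SimulationConfig(seed=7, interventions=(SimulatedEffect("2017-03", -0.10),))
fit = fit_its(simulate_outcome(cfg), cfg.specs)
print(fit.effects["abrupt_2017-03"])   # estimate, SE, 95% CI, p-value
```

## Command line

```bash
alcpolicy affordability --economy econ.csv --base-year 2010 -o afford.csv
alcpolicy timeline validate timeline.json
alcpolicy classify --timeline timeline.json --economy econ.csv -o tiers.csv
alcpolicy score --tiers tiers.csv -o score.csv
alcpolicy rate --ratings ratings.csv --timeline timeline.json -o report.json
alcpolicy simulate outcome --config sim.yaml --seed 1 -o series.csv
alcpolicy evaluate --series series.csv --interventions i.json -o fit.json
alcpolicy report --config run.yaml
```

Exit codes: 0 ok, 1 validation/input error, 2 internal error.

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from the bundled
inputs — loads the annual index table and the 21-event timeline,
classifies every event, builds the monthly cumulative score over
Jan 2000 – Dec 2019 — and writes the resulting headline quantity as
JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/alcpolicy/economics.py` — affordability index and banding
- `src/alcpolicy/timeline.py` — policy event/measure model and I/O
  (JSON schema in `docs/timeline.schema.json`)
- `src/alcpolicy/tiers.py` — eligibility, tier rules, cumulative score
- `src/alcpolicy/ratings.py` — expert-rating aggregation, ICC, Spearman,
  concordance
- `src/alcpolicy/its.py` — design checks, design matrix, segmented
  regression with AR(1) correction
- `src/alcpolicy/simulate.py` — synthetic economy/outcome/ratings
- `src/alcpolicy/pipeline.py`, `src/alcpolicy/cli.py` — orchestration
  and CLI
- `docs/methods.md` — models, assumptions, defaults, limitations
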