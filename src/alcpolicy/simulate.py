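"""Synthetic inputs: economy, monthly outcomes, and expert ratings.

Everything the pipeline consumes can be generated here, so every stage
runs and is testable without external downloads.

Reproducibility: each generator derives independent child streams from
its ``seed`` via ``numpy.random.SeedSequence(seed, spawn_key=...)`` with
fixed spawn keys (documented per generator), so adding a new generator
never shifts the outputs of an existing one, and a fixed seed is
bit-reproducible.

Stated world defaults (monthly outcome): the generator emulates an adult
per-capita alcohol-consumption style series — baseline 1.2 litres pure
alcohol per month, a mild trend, a single-cosine seasonal cycle of
amplitude 0.1, AR(1) noise with rho 0.3 and innovation SD 0.05, over the
240-month window Jan 2000 - Dec 2019.  Intervention effects are steps or
ramps at configured dates.  Expert ratings emulate a five-member panel
on the 0-10 integer scale with rater-level bias SD 1.0 and rating noise
SD 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import EconomicRecord, EconomicSeries
from .its import EffectShape, InterventionSpec, MonthlySeries
from .ratings import RatingItem, RatingMatrix

__all__ = [
    "SimulatedEffect",
    "SimulationConfig",
    "simulate_economy",
    "simulate_outcome",
    "simulate_ratings",
]

# spawn keys per stream (fixed; see module docstring)
_KEY_ECON_INCOME = (0,)
_KEY_OUTCOME_COVARIATE = 1  # (1, i) per covariate, sorted by name
_KEY_OUTCOME_NOISE = (2,)
_KEY_RATING_BIAS = (3,)
_KEY_RATING_NOISE = (4,)


def _rng(seed: int, spawn_key: tuple) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


@dataclass(frozen=True)
class SimulatedEffect:
    """A known-truth policy effect injected into the outcome series."""

    date: str | pd.Period
    true_effect: float
    shape: EffectShape | str = EffectShape.ABRUPT
    lag_months: int | None = None

    @property
    def spec(self) -> InterventionSpec:
        return InterventionSpec(pd.Period(self.date, freq="M"), EffectShape(self.shape), self.lag_months)


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the monthly-outcome generator (defaults = stated world)."""

    seed: int = 0
    start: str = "2000-01"
    end: str = "2019-12"
    baseline_level: float = 1.2
    trend_per_month: float = 0.001
    seasonal_amplitude: float = 0.1
    ar1_rho: float = 0.3
    noise_sd: float = 0.05
    interventions: tuple[SimulatedEffect, ...] = ()
    covariate_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        object.__setattr__(self, "interventions", tuple(self.interventions))
        object.__setattr__(self, "covariate_effects", dict(self.covariate_effects))

    @property
    def specs(self) -> tuple[InterventionSpec, ...]:
        return tuple(e.spec for e in self.interventions)


def simulate_economy(
    target_changes: Sequence[tuple[int, float]],
    base_year: int,
    seed: int = 0,
    income_drift: float = 0.04,
    income_sd: float = 0.02,
) -> EconomicSeries:
    """Income/price index series whose affordability changes hit given targets.

    ``target_changes`` lists ``(year, percent)`` for every year except the
    first of the series (the first simulated year is ``min(year) - 1`` and
    has no change).  The income index follows a multiplicative random walk
    with drift (stream spawn key ``(0,)``); the price index is solved from
    the affordability recursion so that each year-over-year proportional
    change in income/price reproduces its target exactly.  Base-year
    components are normalized to 100; ``base_year`` must lie within the
    simulated range.
    """
    if not target_changes:
        raise ValueError("at least one target change required")
    targets = sorted((int(y), float(v)) for y, v in target_changes)
    years = [y for y, _ in targets]
    for prev, cur in zip(years, years[1:]):
        if cur != prev + 1:
            raise ValueError(f"target years must be consecutive; got {prev} -> {cur}")
    first_year = years[0] - 1
    all_years = [first_year] + years
    if base_year not in all_years:
        raise ValueError(f"base_year {base_year} outside simulated range {first_year}-{years[-1]}")

    rng = _rng(seed, _KEY_ECON_INCOME)
    # affordability ratio path from the recursion a_y = a_{y-1} (1 + v_y/100)
    ratio = [1.0]
    for _, v in targets:
        growth = 1.0 + v / 100.0
        if growth <= 0:
            raise ValueError(f"target change {v}% implies a non-positive index")
        ratio.append(ratio[-1] * growth)
    income = [100.0]
    for _ in years:
        income.append(income[-1] * (1.0 + income_drift + income_sd * rng.standard_normal()))
        if income[-1] <= 0:
            raise ValueError("income walk produced a non-positive index; reduce income_sd")
    price = [inc / a for inc, a in zip(income, ratio)]

    base_pos = all_years.index(base_year)
    income = [100.0 * v / income[base_pos] for v in income]
    price = [100.0 * v / price[base_pos] for v in price]
    records = [
        EconomicRecord(y, inc, pr) for y, inc, pr in zip(all_years, income, price)
    ]
    return EconomicSeries(records, base_year)


def simulate_outcome(config: SimulationConfig) -> MonthlySeries:
    """Monthly outcome: trend + cosine season + policy effects + covariates + AR(1) noise.

    ``value_t = baseline + trend*t + A cos(2 pi month_t / 12)
    + sum_i effect_i(t) + sum_c beta_c x_c(t) + e_t`` with
    ``e_t = rho e_{t-1} + N(0, sd^2)`` (stationary start).  Covariates are
    standardized AR(1) (rho 0.8) paths, one stream per name in sorted
    order (spawn keys ``(1, i)``); noise uses spawn key ``(2,)``.
    """
    months = pd.period_range(config.start, config.end, freq="M")
    n = len(months)
    t = np.arange(n, dtype=float)
    values = (
        config.baseline_level
        + config.trend_per_month * t
        + config.seasonal_amplitude * np.cos(2.0 * np.pi * months.month / 12.0)
    )
    for effect in config.interventions:
        values = values + effect.true_effect * effect.spec.column(months)

    covariates: dict[str, np.ndarray] = {}
    for i, name in enumerate(sorted(config.covariate_effects)):
        rng = _rng(config.seed, (_KEY_OUTCOME_COVARIATE, i))
        z = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = z[0]
        for k in range(1, n):
            x[k] = 0.8 * x[k - 1] + np.sqrt(1 - 0.8**2) * z[k]
        covariates[name] = x
        values = values + config.covariate_effects[name] * x

    rng = _rng(config.seed, _KEY_OUTCOME_NOISE)
    z = rng.standard_normal(n)
    e = np.empty(n)
    rho, sd = config.ar1_rho, config.noise_sd
    e[0] = z[0] * (sd / np.sqrt(1 - rho**2) if sd > 0 else 0.0)
    for k in range(1, n):
        e[k] = rho * e[k - 1] + sd * z[k]
    return MonthlySeries(months, values + e, covariates)


def simulate_ratings(
    true_impacts: Sequence[float],
    n_raters: int = 5,
    rater_sd: float = 1.5,
    rater_bias_sd: float = 1.0,
    seed: int = 0,
    items: Sequence[RatingItem] | None = None,
) -> RatingMatrix:
    """Integer 0-10 expert ratings around known per-item true impacts.

    ``rating = clip(round(true_impact + bias_r + noise), 0, 10)`` with a
    per-rater bias ``N(0, rater_bias_sd^2)`` (spawn key ``(3,)``) and cell
    noise ``N(0, rater_sd^2)`` (spawn key ``(4,)``).
    """
    impacts = np.asarray(true_impacts, dtype=float)
    if ((impacts < 0) | (impacts > 10)).any():
        raise ValueError("true impacts must lie in [0, 10]")
    if n_raters < 2:
        raise ValueError("n_raters must be >= 2")
    if items is None:
        items = [RatingItem(event_id=f"item{i:02d}") for i in range(len(impacts))]
    elif len(items) != len(impacts):
        raise ValueError("items and true_impacts length mismatch")

    bias = _rng(seed, _KEY_RATING_BIAS).normal(0.0, rater_bias_sd, size=n_raters)
    noise = _rng(seed, _KEY_RATING_NOISE).normal(0.0, rater_sd, size=(len(impacts), n_raters))
    raw = impacts[:, None] + bias[None, :] + noise
    values = np.clip(np.round(raw), 0, 10)
    raters = [f"rater{j+1}" for j in range(n_raters)]
    return RatingMatrix(items, raters, values)
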