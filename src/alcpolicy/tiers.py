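"""Objective tier classification of policy events and the cumulative score.

Each dated policy event is assigned to one of four classes:

``tier1``
    Highly effective general-population interventions with an expected
    immediate impact: a restrictive tax/price measure whose enactment
    year saw a *decrease* in alcohol affordability, or a restrictive
    general-population availability measure limiting daily sales hours.
``tier2_only``
    Other general-population interventions with smaller expected
    effects: a restrictive tax/price measure with a small (< threshold)
    affordability increase, or availability restrictions limited to
    certain days or night hours.  (Every tier-1 event also satisfies a
    tier-2 criterion; ``tier2_only`` marks events qualifying *only* at
    tier 2.)
``specific``
    Events whose measures all target a specific population group; they
    are analysed against group-specific outcomes, never scored.
``excluded``
    Liberalizing events, events without enough pre/post observation
    months for a powered interrupted-time-series analysis, and events
    meeting no criterion (e.g. a marketing ban alone, whose effect is
    delayed).

Scored events are summed into a monthly cumulative policy-score step
function (tier-1 weight 1.0, tier-2-only weight 0.5), which can serve as
a single exposure regressor in evaluation models.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import (
    DEFAULT_THRESHOLD,
    ChangeCategory,
    EconomicSeries,
    affordability_change,
    categorize_change,
)
from .timeline import AvailabilityScope, Direction, Domain, PolicyEvent, Population

__all__ = [
    "DEFAULT_WEIGHTS",
    "Tier",
    "Criterion",
    "StudyWindow",
    "Eligibility",
    "TierAssignment",
    "ScoreSeries",
    "check_eligibility",
    "classify",
    "cumulative_score",
]

#: Score contributed by each scored tier at its enactment month.
DEFAULT_WEIGHTS: Mapping[str, float] = {"tier1": 1.0, "tier2_only": 0.5}


class Tier(str, enum.Enum):
    TIER1 = "tier1"
    TIER2_ONLY = "tier2_only"
    SPECIFIC = "specific"
    EXCLUDED = "excluded"


class Criterion(str, enum.Enum):
    AFFORDABILITY_DECREASE = "affordability_decrease"
    AFFORDABILITY_SMALL_INCREASE = "affordability_small_increase"
    AVAILABILITY_MAJOR = "availability_major"
    AVAILABILITY_MINOR = "availability_minor"
    WINDOW_INELIGIBLE = "window_ineligible"
    LIBERALIZING = "liberalizing"
    SPECIFIC_POPULATION = "specific_population"
    NO_CRITERION = "no_criterion"


_TIER1_CRITERIA = {Criterion.AFFORDABILITY_DECREASE, Criterion.AVAILABILITY_MAJOR}
_TIER2_CRITERIA = {Criterion.AFFORDABILITY_SMALL_INCREASE, Criterion.AVAILABILITY_MINOR}


@dataclass(frozen=True)
class StudyWindow:
    """Monthly observation window with minimum pre/post series lengths.

    The defaults require at least 24 monthly observations on each side
    of an intervention; 50-100 total time points are recommended for a
    segmented-regression evaluation.
    """

    start: pd.Period
    end: pd.Period
    min_pre: int = 24
    min_post: int = 24
    recommended_total_min: int = 50
    recommended_total_max: int = 100

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Period(self.start, freq="M"))
        object.__setattr__(self, "end", pd.Period(self.end, freq="M"))
        if not self.start < self.end:
            raise ValueError(f"window start {self.start} must precede end {self.end}")
        if self.min_pre < 1 or self.min_post < 1:
            raise ValueError("min_pre and min_post must be >= 1")

    @classmethod
    def from_strings(cls, start: str, end: str, **kwargs) -> "StudyWindow":
        return cls(pd.Period(start, freq="M"), pd.Period(end, freq="M"), **kwargs)

    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, self.end, freq="M")

    @property
    def n_months(self) -> int:
        return (self.end - self.start).n + 1


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: str | None  # None | out_of_window | insufficient_pre | insufficient_post
    pre_months: int
    post_months: int


@dataclass(frozen=True)
class TierAssignment:
    """Classification outcome for one event, with the criteria that fired."""

    event_id: str
    enactment_date: dt.date
    tier: Tier
    criteria_fired: tuple[Criterion, ...]
    affordability_change_used: float | None = None


@dataclass(frozen=True)
class ScoreSeries:
    """Monthly cumulative policy-score step function."""

    series: pd.Series  # PeriodIndex (M) -> float
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def value_at(self, month) -> float:
        return float(self.series.loc[pd.Period(month, freq="M")])

    @property
    def months(self) -> pd.PeriodIndex:
        return self.series.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.series.index.astype(str), "score": self.series.to_numpy()}
        )


def _event_month(event: PolicyEvent | dt.date) -> pd.Period:
    date = event.enactment_date if isinstance(event, PolicyEvent) else event
    return pd.Period(year=date.year, month=date.month, freq="M")


def check_eligibility(event: PolicyEvent | dt.date, window: StudyWindow) -> Eligibility:
    """Does the window leave enough months before and after the event?

    Pre-months are counted strictly before the enactment month; post-months
    from the enactment month to the window end, inclusive (the enactment
    month is the first month the policy can act on).
    """
    month = _event_month(event)
    if month < window.start or month > window.end:
        return Eligibility(False, "out_of_window", 0, 0)
    pre = (month - window.start).n
    post = (window.end - month).n + 1
    if pre < window.min_pre:
        return Eligibility(False, "insufficient_pre", pre, post)
    if post < window.min_post:
        return Eligibility(False, "insufficient_post", pre, post)
    return Eligibility(True, None, pre, post)


def _evaluate_criteria(
    event: PolicyEvent,
    econ: EconomicSeries | None,
    threshold: float,
) -> tuple[set[Criterion], float | None]:
    """Tier criteria fired by the event's restrictive general-population measures."""
    fired: set[Criterion] = set()
    change_used: float | None = None
    for m in event.measures:
        if m.direction != Direction.RESTRICTIVE or m.population != Population.GENERAL:
            continue
        if m.domain == Domain.TAXATION_PRICE:
            if econ is None:
                raise ValueError(
                    f"missing economic data for taxation event in year {event.enactment_date.year}"
                )
            year = event.enactment_date.year
            try:
                change = affordability_change(econ, year)
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"missing economic data for year {year} (event {event.event_id})"
                ) from exc
            change_used = change
            cat = categorize_change(change, threshold)
            if cat is ChangeCategory.DECREASE:
                fired.add(Criterion.AFFORDABILITY_DECREASE)
            elif cat is ChangeCategory.SMALL_INCREASE:
                fired.add(Criterion.AFFORDABILITY_SMALL_INCREASE)
        elif m.domain == Domain.AVAILABILITY:
            if m.availability_scope == AvailabilityScope.DAILY_HOURS:
                fired.add(Criterion.AVAILABILITY_MAJOR)
            elif m.availability_scope == AvailabilityScope.SPECIFIC_DAYS_OR_NIGHT:
                fired.add(Criterion.AVAILABILITY_MINOR)
        # marketing/advertising alone is delayed-impact: never a criterion;
        # drink-driving and 'other' follow harm pathways outside the score.
    return fired, change_used


def _classify_event(
    event: PolicyEvent,
    econ: EconomicSeries | None,
    window: StudyWindow,
    threshold: float,
) -> TierAssignment:
    any_liberalizing = any(m.direction == Direction.LIBERALIZING for m in event.measures)
    all_specific = all(m.population == Population.SPECIFIC for m in event.measures)

    if any_liberalizing:
        fired, change_used = _evaluate_criteria(event, econ, threshold)
        if not fired:
            return TierAssignment(
                event.event_id, event.enactment_date, Tier.EXCLUDED,
                (Criterion.LIBERALIZING,), change_used,
            )
    if all_specific:
        return TierAssignment(
            event.event_id, event.enactment_date, Tier.SPECIFIC,
            (Criterion.SPECIFIC_POPULATION,),
        )
    elig = check_eligibility(event, window)
    if not elig.eligible:
        return TierAssignment(
            event.event_id, event.enactment_date, Tier.EXCLUDED,
            (Criterion.WINDOW_INELIGIBLE,),
        )
    fired, change_used = _evaluate_criteria(event, econ, threshold)
    ordered = tuple(c for c in Criterion if c in fired)
    if fired & _TIER1_CRITERIA:
        return TierAssignment(
            event.event_id, event.enactment_date, Tier.TIER1, ordered, change_used
        )
    if fired & _TIER2_CRITERIA:
        return TierAssignment(
            event.event_id, event.enactment_date, Tier.TIER2_ONLY, ordered, change_used
        )
    return TierAssignment(
        event.event_id, event.enactment_date, Tier.EXCLUDED,
        (Criterion.NO_CRITERION,), change_used,
    )


def classify(
    events: Iterable[PolicyEvent],
    econ: EconomicSeries | None,
    window: StudyWindow,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[TierAssignment]:
    """Assign every event a tier, in enactment-date order.

    ``econ`` may be ``None`` only if no restrictive general-population
    tax/price measure needs an affordability lookup; a missing year in
    the economic series raises an error naming it.
    """
    ordered = sorted(events, key=lambda e: e.enactment_date)
    return [_classify_event(ev, econ, window, threshold) for ev in ordered]


def cumulative_score(
    assignments: Sequence[TierAssignment],
    window: StudyWindow,
    weights: Mapping[str, float] | None = None,
) -> ScoreSeries:
    """Monthly cumulative policy score over the window.

    Each scored event adds its tier weight from its enactment month
    (inclusive) onward; mid-month enactments take effect that calendar
    month.  Events after the window end contribute nothing; events
    before the window start contribute to every month.
    """
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    months = window.months()
    score = np.zeros(len(months))
    for a in assignments:
        w = weights.get(a.tier.value)
        if not w:
            continue
        month = _event_month(a.enactment_date)
        if month > window.end:
            continue
        start_pos = max(0, (month - window.start).n)
        score[start_pos:] += w
    return ScoreSeries(pd.Series(score, index=months), weights)
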