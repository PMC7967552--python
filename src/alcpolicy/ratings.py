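"""Expert impact ratings: aggregation, reliability, and concordance.

A panel of experts independently rates every policy measure on a 0-10
impact scale (modified nominal group technique: no interactive meeting).
This module aggregates the ratings, selects enactment dates whose best
measure averages at or above a threshold, quantifies interrater
agreement, and compares the expert selection with the criteria-based
tier classification.

Interrater reliability uses the single-rater, absolute-agreement,
two-way random-effects intraclass correlation ICC(2,1).  With ``n``
items and ``k`` raters and the usual two-way ANOVA mean squares
(``MSR`` between items, ``MSC`` between raters, ``MSE`` residual)::

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

The 95% confidence interval is the standard F-based interval for this
variant.  Pairwise Spearman rank correlations (average ranks for ties)
are summarised by their median and interquartile range.
"""

from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tiers import Tier, TierAssignment
from .timeline import PolicyEvent

__all__ = [
    "RatingItem",
    "RatingMatrix",
    "ICCResult",
    "SpearmanSummary",
    "ReliabilityReport",
    "Concordance",
    "mean_ratings",
    "select_dates",
    "icc",
    "spearman_summary",
    "reliability_report",
    "concordance",
    "read_ratings_csv",
    "write_ratings_csv",
]

RATING_MIN, RATING_MAX = 0.0, 10.0


@dataclass(frozen=True)
class RatingItem:
    """One rated object: a measure within a policy event."""

    event_id: str
    measure_index: int = 0
    description: str = ""


@dataclass(frozen=True)
class RatingMatrix:
    """Items x raters matrix of 0-10 ratings (integer or half-point).

    Missing cells (NaN) are rejected unless ``allow_missing`` is set, in
    which case per-item means use the available raters and are flagged.
    """

    items: tuple[RatingItem, ...]
    raters: tuple[str, ...]
    values: np.ndarray  # shape (n_items, n_raters)
    allow_missing: bool = False

    def __init__(self, items, raters, values, allow_missing: bool = False):
        object.__setattr__(self, "items", tuple(items))
        object.__setattr__(self, "raters", tuple(raters))
        object.__setattr__(self, "values", np.asarray(values, dtype=float))
        object.__setattr__(self, "allow_missing", bool(allow_missing))
        self._validate()

    def _validate(self) -> None:
        if len(self.raters) < 2:
            raise ValueError("at least 2 raters required")
        if len(self.items) < 2:
            raise ValueError("at least 2 items required")
        if self.values.shape != (len(self.items), len(self.raters)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.items)} items x {len(self.raters)} raters"
            )
        nan = np.isnan(self.values)
        if nan.any() and not self.allow_missing:
            raise ValueError("missing ratings present; pass allow_missing=True to permit")
        finite = self.values[~nan]
        if ((finite < RATING_MIN) | (finite > RATING_MAX)).any():
            raise ValueError(f"ratings must lie in [{RATING_MIN:g}, {RATING_MAX:g}]")
        if not np.allclose(finite * 2, np.round(finite * 2), atol=1e-9):
            raise ValueError("ratings must be on an integer or half-point scale")

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95
    variant: str = "ICC(2,1)"


@dataclass(frozen=True)
class SpearmanSummary:
    pairs: tuple[tuple[str, str, float], ...]
    median: float
    iqr: float
    excluded_pairs: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class ReliabilityReport:
    icc: ICCResult
    spearman: SpearmanSummary
    incomplete: bool = False

    def to_dict(self) -> dict:
        return {
            "icc": {
                "estimate": self.icc.estimate,
                "ci_low": self.icc.ci_low,
                "ci_high": self.icc.ci_high,
                "confidence": self.icc.confidence,
                "variant": self.icc.variant,
            },
            "spearman": {
                "pairs": [list(p) for p in self.spearman.pairs],
                "median": self.spearman.median,
                "iqr": self.spearman.iqr,
                "excluded_pairs": [list(p) for p in self.spearman.excluded_pairs],
            },
            "incomplete": self.incomplete,
        }


def mean_ratings(m: RatingMatrix) -> np.ndarray:
    """Arithmetic mean over raters per item (available raters if missing allowed)."""
    if m.complete:
        return m.values.mean(axis=1)
    return np.nanmean(m.values, axis=1)


def select_dates(
    m: RatingMatrix,
    events: Sequence[PolicyEvent],
    threshold: float = 5.0,
) -> set[dt.date]:
    """Enactment dates where some measure's mean rating is >= threshold (inclusive)."""
    by_id = {ev.event_id: ev for ev in events}
    means = mean_ratings(m)
    best: dict[dt.date, float] = {}
    for item, mean in zip(m.items, means):
        ev = by_id.get(item.event_id)
        if ev is None:
            raise ValueError(f"rating item references unknown event {item.event_id!r}")
        date = ev.enactment_date
        best[date] = max(best.get(date, -np.inf), mean)
    return {date for date, mean in best.items() if mean >= threshold}


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (items, raters, residual) of a complete matrix."""
    n, k = x.shape
    grand = x.mean()
    ss_items = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_raters = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_resid = ss_total - ss_items - ss_raters
    msr = ss_items / (n - 1)
    msc = ss_raters / (k - 1)
    mse = ss_resid / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(m: RatingMatrix, confidence: float = 0.95) -> ICCResult:
    """Single-rater absolute-agreement ICC(2,1) with F-based confidence interval."""
    if not m.complete:
        raise ValueError("ICC requires a complete matrix")
    x = m.values
    n, k = x.shape
    if np.ptp(x) == 0:
        raise ValueError("degenerate matrix: no variance in ratings")
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ValueError("degenerate matrix: non-positive ICC denominator")
    est = (msr - mse) / denom

    alpha = 1.0 - confidence
    if est >= 1.0 or (msc <= 0 and mse <= 0):
        # perfect agreement: no rater or residual variance, interval collapses
        return ICCResult(float(est), float(est), float(est), confidence)
    # Satterthwaite degrees of freedom for the F interval (McGraw & Wong)
    a = k * est / (n * (1.0 - est))
    b = 1.0 + k * est * (n - 1.0) / (n * (1.0 - est))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    lower = float(np.clip(lower, -1.0, est)) if np.isfinite(lower) else float(est)
    upper = float(np.clip(upper, est, 1.0)) if np.isfinite(upper) else float(est)
    return ICCResult(float(est), lower, upper, confidence)


def spearman_summary(m: RatingMatrix) -> SpearmanSummary:
    """Pairwise Spearman rho for all rater pairs; median and IQR of the list.

    Pairs involving a rater with constant ratings have undefined rho and
    are excluded (and reported as such).
    """
    pairs: list[tuple[str, str, float]] = []
    excluded: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(len(m.raters)), 2):
        xi, xj = m.values[:, i], m.values[:, j]
        mask = ~(np.isnan(xi) | np.isnan(xj))
        if np.ptp(xi[mask]) == 0 or np.ptp(xj[mask]) == 0 or mask.sum() < 2:
            excluded.append((m.raters[i], m.raters[j]))
            continue
        rho = stats.spearmanr(xi[mask], xj[mask]).statistic
        pairs.append((m.raters[i], m.raters[j], float(rho)))
    if not pairs:
        raise ValueError("no rater pair with defined Spearman correlation")
    rhos = np.array([p[2] for p in pairs])
    q1, q3 = np.percentile(rhos, [25, 75])
    return SpearmanSummary(
        tuple(pairs), float(np.median(rhos)), float(q3 - q1), tuple(excluded)
    )


def reliability_report(m: RatingMatrix, confidence: float = 0.95) -> ReliabilityReport:
    """ICC(2,1) and the Spearman pair summary in one report."""
    return ReliabilityReport(
        icc=icc(m, confidence),
        spearman=spearman_summary(m),
        incomplete=not m.complete,
    )


@dataclass(frozen=True)
class Concordance:
    """Partition of expert-selected vs criteria-selected enactment dates."""

    in_both: frozenset
    expert_only: frozenset
    criteria_only: frozenset

    @property
    def expert_superset(self) -> bool:
        return not self.criteria_only

    def to_dict(self) -> dict:
        key = lambda d: d.isoformat() if hasattr(d, "isoformat") else str(d)
        return {
            "in_both": sorted(map(key, self.in_both)),
            "expert_only": sorted(map(key, self.expert_only)),
            "criteria_only": sorted(map(key, self.criteria_only)),
            "expert_superset": self.expert_superset,
        }


def concordance(
    expert_dates: Iterable[dt.date],
    tier_assignments: Sequence[TierAssignment],
) -> Concordance:
    """Compare expert-selected dates with the dates of scored (tier 1/2) events."""
    expert = frozenset(expert_dates)
    criteria = frozenset(
        a.enactment_date for a in tier_assignments if a.tier in (Tier.TIER1, Tier.TIER2_ONLY)
    )
    return Concordance(
        in_both=expert & criteria,
        expert_only=expert - criteria,
        criteria_only=criteria - expert,
    )


def read_ratings_csv(path: str | Path) -> RatingMatrix:
    """Read a ratings CSV: ``event_id,measure_no,description,<rater>,...``."""
    frame = pd.read_csv(path)
    meta_cols = [c for c in ("event_id", "measure_no", "description") if c in frame.columns]
    if "event_id" not in meta_cols:
        raise ValueError("ratings CSV must have an 'event_id' column")
    rater_cols = [c for c in frame.columns if c not in meta_cols]
    if len(rater_cols) < 2:
        raise ValueError("ratings CSV must have at least 2 rater columns")
    items = [
        RatingItem(
            event_id=str(row.event_id),
            measure_index=int(getattr(row, "measure_no", 0) or 0),
            description=str(getattr(row, "description", "") or ""),
        )
        for row in frame.itertuples()
    ]
    values = frame[rater_cols].to_numpy(dtype=float)
    return RatingMatrix(items, rater_cols, values, allow_missing=np.isnan(values).any())


def write_ratings_csv(m: RatingMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "event_id": [it.event_id for it in m.items],
            "measure_no": [it.measure_index for it in m.items],
            "description": [it.description for it in m.items],
        }
    )
    for j, rater in enumerate(m.raters):
        frame[rater] = m.values[:, j]
    frame.to_csv(path, index=False)
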