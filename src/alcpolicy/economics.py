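"""Affordability of alcohol from income and price index series.

The affordability index is the ratio of a disposable-income index to an
alcohol-price index, both scaled to a common base year (index = 100).
Alcohol becomes *more* affordable when income grows faster than alcohol
prices.  An excise-tax rise only counts as a price intervention with
immediate population-level bite when affordability *falls* in the
enactment year; tax rises swallowed by income growth do not.

Year-over-year proportional change in affordability for year ``y``::

    change(y) = 100 * ( (I_y / P_y) - (I_{y-1} / P_{y-1}) ) / (I_{y-1} / P_{y-1})

where ``I`` is the disposable-income index and ``P`` the alcohol-price
index.  Positive values mean alcohol became more affordable.  Changes are
banded into three categories used by the tier rules: any decrease, a
small increase below a threshold (default 5 %), and a large increase.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLD",
    "ChangeCategory",
    "EconomicRecord",
    "EconomicSeries",
    "AffordabilityRecord",
    "affordability_levels",
    "affordability_change",
    "affordability_table",
    "categorize_change",
    "read_economy_csv",
    "write_affordability_csv",
]

#: Affordability-growth threshold (percent) separating "small" from "large"
#: increases; the median affordability change over the study period.
DEFAULT_THRESHOLD = 5.0

#: Tolerance for the base-year components being exactly 100.
_BASE_TOL = 0.05


class ChangeCategory(str, enum.Enum):
    """Band of a year-over-year affordability change."""

    DECREASE = "decrease"
    SMALL_INCREASE = "small_increase"
    LARGE_INCREASE = "large_increase"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class EconomicRecord:
    """One year of base-scaled income and alcohol-price indices."""

    year: int
    income_index: float
    price_index: float


@dataclass(frozen=True)
class EconomicSeries:
    """Consecutive annual income and alcohol-price indices.

    Parameters
    ----------
    records
        Annual records with strictly increasing, gap-free years.
    base_year
        The year at which both indices are scaled to 100.  If the base
        year lies inside the record range, its components must be 100
        (within 0.05); if it lies outside, the indices are assumed to be
        already base-scaled.
    """

    records: tuple[EconomicRecord, ...]
    base_year: int

    def __init__(self, records: Iterable[EconomicRecord], base_year: int):
        object.__setattr__(self, "records", tuple(records))
        object.__setattr__(self, "base_year", int(base_year))
        self._validate()

    def _validate(self) -> None:
        if not self.records:
            raise ValueError("no data: economic series is empty")
        years = [r.year for r in self.records]
        for prev, cur in zip(years, years[1:]):
            if cur != prev + 1:
                raise ValueError(
                    f"years must be consecutive and increasing; got {prev} -> {cur}"
                )
        for r in self.records:
            if not (r.income_index > 0 and r.price_index > 0) or not (
                math.isfinite(r.income_index) and math.isfinite(r.price_index)
            ):
                raise ValueError(f"invalid index: non-positive value in year {r.year}")
        base = self._record(self.base_year)
        if base is not None:
            if abs(base.income_index - 100.0) > _BASE_TOL or abs(base.price_index - 100.0) > _BASE_TOL:
                raise ValueError(
                    f"base year {self.base_year} components must equal 100, got "
                    f"income={base.income_index}, price={base.price_index}"
                )

    def _record(self, year: int) -> EconomicRecord | None:
        for r in self.records:
            if r.year == year:
                return r
        return None

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(r.year for r in self.records)

    def __contains__(self, year: int) -> bool:
        return self._record(year) is not None

    def raw_ratio(self, year: int) -> float:
        """Income/price ratio for ``year`` (unnormalized)."""
        rec = self._record(year)
        if rec is None:
            raise KeyError(f"year {year} not in series")
        return rec.income_index / rec.price_index

    def rebased(self, income_factor: float, price_factor: float) -> "EconomicSeries":
        """Return a copy with all income (price) indices scaled by a constant.

        Proportional affordability changes are invariant under rebasing.
        Note the scaled series generally violates the base-year = 100
        convention, so the base-year check is only applied when the
        factors preserve it.
        """
        recs = [
            replace(r, income_index=r.income_index * income_factor,
                    price_index=r.price_index * price_factor)
            for r in self.records
        ]
        # keep base_year outside the range check by shifting it if scaling broke 100
        base = self._record(self.base_year)
        base_year = self.base_year
        if base is not None and (abs(income_factor - 1) > 1e-12 or abs(price_factor - 1) > 1e-12):
            base_year = self.records[0].year - 1  # sentinel: base outside range
        return EconomicSeries(recs, base_year)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, base_year: int) -> "EconomicSeries":
        required = {"year", "income_index", "price_index"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"economy table missing columns: {sorted(missing)}")
        recs = [
            EconomicRecord(int(row.year), float(row.income_index), float(row.price_index))
            for row in frame.sort_values("year").itertuples()
        ]
        return cls(recs, base_year)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [r.year for r in self.records],
                "income_index": [r.income_index for r in self.records],
                "price_index": [r.price_index for r in self.records],
            }
        )


@dataclass(frozen=True)
class AffordabilityRecord:
    """Affordability level (base year = 100) and optional change for one year.

    ``change_pct`` is ``None`` for the first year of a series (no prior
    year to compare against; it is deliberately not imputed as zero).
    ``display_level`` / ``display_change`` give the table-style rounding
    (integer level, one-decimal percent); comparisons against the
    categorisation threshold always use the unrounded value.
    """

    year: int
    index_level: float
    change_pct: float | None = None
    category: ChangeCategory | None = None

    @property
    def display_level(self) -> int:
        return round(self.index_level)

    @property
    def display_change(self) -> float | None:
        return None if self.change_pct is None else round(self.change_pct, 1)


def _base_ratio(series: EconomicSeries) -> float:
    if series.base_year in series:
        return series.raw_ratio(series.base_year)
    return 1.0  # indices already base-scaled: 100/100


def affordability_levels(series: EconomicSeries) -> list[AffordabilityRecord]:
    """Affordability index level per year, base year = 100 (levels only)."""
    base = _base_ratio(series)
    return [
        AffordabilityRecord(year=r.year, index_level=100.0 * series.raw_ratio(r.year) / base)
        for r in series.records
    ]


def affordability_change(series: EconomicSeries, year: int) -> float:
    """Percent change in affordability from ``year - 1`` to ``year``.

    Positive values mean alcohol became more affordable.  Raises if the
    prior year is absent from the series.
    """
    if year not in series:
        raise KeyError(f"year {year} not in series")
    if (year - 1) not in series:
        raise ValueError(f"no prior year: cannot compute change for {year}")
    prev = series.raw_ratio(year - 1)
    return 100.0 * (series.raw_ratio(year) - prev) / prev


def categorize_change(change_pct: float, threshold: float = DEFAULT_THRESHOLD) -> ChangeCategory:
    """Band an affordability change: decrease / small (< threshold) / large.

    The lower bound of ``small_increase`` is inclusive at 0, the upper
    bound exclusive at ``threshold``; the unrounded change is compared.
    """
    if not math.isfinite(change_pct):
        raise ValueError("change_pct must be finite")
    if change_pct < 0:
        return ChangeCategory.DECREASE
    if change_pct < threshold:
        return ChangeCategory.SMALL_INCREASE
    return ChangeCategory.LARGE_INCREASE


def affordability_table(
    series: EconomicSeries, threshold: float = DEFAULT_THRESHOLD
) -> list[AffordabilityRecord]:
    """Levels, changes and categories for every year of the series."""
    out = []
    for rec in affordability_levels(series):
        if (rec.year - 1) in series:
            change = affordability_change(series, rec.year)
            rec = replace(rec, change_pct=change, category=categorize_change(change, threshold))
        out.append(rec)
    return out


def read_economy_csv(path: str | Path, base_year: int) -> EconomicSeries:
    """Read ``year,income_index,price_index`` CSV into an :class:`EconomicSeries`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"economy file not found: {path}")
    return EconomicSeries.from_frame(pd.read_csv(path), base_year)


def write_affordability_csv(
    records: Sequence[AffordabilityRecord], path: str | Path
) -> None:
    """Write ``year,index_level,change_pct,category`` CSV (full precision)."""
    pd.DataFrame(
        {
            "year": [r.year for r in records],
            "index_level": [r.index_level for r in records],
            "change_pct": [r.change_pct for r in records],
            "category": [r.category.value if r.category else "" for r in records],
        }
    ).to_csv(path, index=False)
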