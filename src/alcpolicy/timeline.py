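"""Data model and I/O for dated alcohol-control policy events.

A policy *event* is everything enacted on one calendar date; it bundles
one or more typed *measures*.  Each measure carries the attributes the
downstream rules engine consumes:

``domain``
    taxation/price, availability, marketing/advertising, drink-driving,
    or other.
``direction``
    restrictive (expected to reduce consumption), liberalizing
    (expected to increase it), or neutral (administrative).
``population``
    general population vs a specific group (with the group named).
``availability_scope``
    for availability measures only: daily sales-hour limits, limits on
    specific days or night hours, outlet-type bans, or
    production/licensing rules.
``immediacy``
    whether the bulk of the expected impact is immediate (price,
    availability) or delayed (advertising bans, education).

Two serialisations are supported: nested JSON (events containing
measures) and a flat CSV with one measure per row and the event fields
repeated.  Loading validates every invariant and reports the offending
event/row and field.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import json
from pathlib import Path
from typing import Iterable, Sequence

import pydantic
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Domain",
    "Direction",
    "Population",
    "AvailabilityScope",
    "Immediacy",
    "PolicyMeasure",
    "PolicyEvent",
    "TimelineError",
    "load_timeline",
    "write_timeline",
    "filter_events",
    "timeline_schema",
]


class TimelineError(ValueError):
    """Raised when a timeline file violates the schema or an invariant."""


class Domain(str, enum.Enum):
    TAXATION_PRICE = "taxation_price"
    AVAILABILITY = "availability"
    MARKETING_ADVERTISING = "marketing_advertising"
    DRINK_DRIVING = "drink_driving"
    OTHER = "other"


class Direction(str, enum.Enum):
    RESTRICTIVE = "restrictive"
    LIBERALIZING = "liberalizing"
    NEUTRAL = "neutral"


class Population(str, enum.Enum):
    GENERAL = "general"
    SPECIFIC = "specific"


class AvailabilityScope(str, enum.Enum):
    DAILY_HOURS = "daily_hours"
    SPECIFIC_DAYS_OR_NIGHT = "specific_days_or_night"
    OUTLET_TYPE = "outlet_type"
    PRODUCTION_LICENSING = "production_licensing"
    NONE = "none"


class Immediacy(str, enum.Enum):
    IMMEDIATE = "immediate"
    DELAYED = "delayed"


class PolicyMeasure(BaseModel):
    """One typed measure within a policy event."""

    model_config = pydantic.ConfigDict(use_enum_values=False, frozen=True)

    domain: Domain
    direction: Direction
    population: Population
    specific_group: str = ""
    availability_scope: AvailabilityScope = AvailabilityScope.NONE
    immediacy: Immediacy = Immediacy.IMMEDIATE
    description: str = ""

    @model_validator(mode="after")
    def _cross_field_rules(self) -> "PolicyMeasure":
        if (self.availability_scope != AvailabilityScope.NONE) != (
            self.domain == Domain.AVAILABILITY
        ):
            raise ValueError(
                "availability_scope must be set exactly when domain is 'availability' "
                f"(domain={self.domain.value}, scope={self.availability_scope.value})"
            )
        if bool(self.specific_group.strip()) != (self.population == Population.SPECIFIC):
            raise ValueError(
                "specific_group must be non-empty exactly when population is 'specific'"
            )
        return self


class PolicyEvent(BaseModel):
    """All measures enacted on one date."""

    model_config = pydantic.ConfigDict(frozen=True)

    event_id: str = Field(min_length=1)
    enactment_date: dt.date
    measures: tuple[PolicyMeasure, ...] = Field(min_length=1)
    notes: str = ""

    @field_validator("enactment_date", mode="before")
    @classmethod
    def _parse_date(cls, v):
        if isinstance(v, str):
            return dt.date.fromisoformat(v)
        return v


def _check_unique_dates(events: Sequence[PolicyEvent]) -> None:
    seen: dict[dt.date, str] = {}
    for ev in events:
        if ev.enactment_date in seen:
            raise TimelineError(
                f"duplicate enactment date {ev.enactment_date} "
                f"(events {seen[ev.enactment_date]!r} and {ev.event_id!r})"
            )
        seen[ev.enactment_date] = ev.event_id


_CSV_COLUMNS = [
    "event_id",
    "enactment_date",
    "notes",
    "domain",
    "direction",
    "population",
    "specific_group",
    "availability_scope",
    "immediacy",
    "description",
]


def _load_json(path: Path) -> list[PolicyEvent]:
    payload = json.loads(path.read_text())
    raw_events = payload.get("events", payload) if isinstance(payload, dict) else payload
    events = []
    for i, raw in enumerate(raw_events):
        try:
            events.append(PolicyEvent.model_validate(raw))
        except pydantic.ValidationError as exc:
            err = exc.errors()[0]
            loc = ".".join(str(p) for p in err["loc"])
            raise TimelineError(
                f"event {i} ({raw.get('event_id', '?')}): field '{loc}': {err['msg']}"
            ) from exc
    return events


def _load_csv(path: Path) -> list[PolicyEvent]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TimelineError(f"{path}: empty file, header required")
        missing = set(_CSV_COLUMNS[:2] + _CSV_COLUMNS[3:6]) - set(reader.fieldnames)
        if missing:
            raise TimelineError(f"{path}: missing columns {sorted(missing)}")
        rows = list(reader)

    grouped: dict[str, dict] = {}
    for lineno, row in enumerate(rows, start=2):
        eid = (row.get("event_id") or "").strip()
        if not eid:
            raise TimelineError(f"row {lineno}: field 'event_id': must be non-empty")
        measure = {
            k: (row.get(k) or "").strip()
            for k in ("domain", "direction", "population", "specific_group",
                      "availability_scope", "immediacy", "description")
        }
        if not measure["availability_scope"]:
            measure["availability_scope"] = "none"
        if not measure["immediacy"]:
            measure["immediacy"] = "immediate"
        try:
            m = PolicyMeasure.model_validate(measure)
        except pydantic.ValidationError as exc:
            err = exc.errors()[0]
            loc = ".".join(str(p) for p in err["loc"]) or "measure"
            raise TimelineError(f"row {lineno}: field '{loc}': {err['msg']}") from exc
        entry = grouped.setdefault(
            eid,
            {
                "event_id": eid,
                "enactment_date": (row.get("enactment_date") or "").strip(),
                "notes": (row.get("notes") or "").strip(),
                "measures": [],
            },
        )
        if entry["enactment_date"] != (row.get("enactment_date") or "").strip():
            raise TimelineError(
                f"row {lineno}: event {eid!r} has inconsistent enactment_date values"
            )
        entry["measures"].append(m)

    events = []
    for eid, entry in grouped.items():
        try:
            events.append(PolicyEvent.model_validate(entry))
        except pydantic.ValidationError as exc:
            err = exc.errors()[0]
            loc = ".".join(str(p) for p in err["loc"])
            raise TimelineError(f"event {eid!r}: field '{loc}': {err['msg']}") from exc
    return events


def load_timeline(path: str | Path) -> list[PolicyEvent]:
    """Load and validate a timeline (JSON or CSV), sorted by enactment date.

    Raises :class:`TimelineError` naming the offending row/event and field
    on any schema violation, and on duplicate enactment dates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"timeline file not found: {path}")
    if path.suffix.lower() == ".json":
        events = _load_json(path)
    elif path.suffix.lower() == ".csv":
        events = _load_csv(path)
    else:
        raise TimelineError(f"unsupported timeline format: {path.suffix!r}")
    _check_unique_dates(events)
    return sorted(events, key=lambda e: e.enactment_date)


def write_timeline(events: Sequence[PolicyEvent], path: str | Path) -> None:
    """Write events as nested JSON or flat CSV, chosen by file suffix."""
    path = Path(path)
    _check_unique_dates(events)
    events = sorted(events, key=lambda e: e.enactment_date)
    if path.suffix.lower() == ".json":
        payload = {"events": [json.loads(e.model_dump_json()) for e in events]}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for ev in events:
                for m in ev.measures:
                    writer.writerow(
                        {
                            "event_id": ev.event_id,
                            "enactment_date": ev.enactment_date.isoformat(),
                            "notes": ev.notes,
                            "domain": m.domain.value,
                            "direction": m.direction.value,
                            "population": m.population.value,
                            "specific_group": m.specific_group,
                            "availability_scope": m.availability_scope.value,
                            "immediacy": m.immediacy.value,
                            "description": m.description,
                        }
                    )
    else:
        raise TimelineError(f"unsupported timeline format: {path.suffix!r}")


def _coerce(value, enum_cls, name: str):
    if value is None or isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError as exc:
        valid = ", ".join(e.value for e in enum_cls)
        raise ValueError(f"unknown {name} {value!r}; expected one of: {valid}") from exc


def filter_events(
    events: Iterable[PolicyEvent],
    direction: Direction | str | None = None,
    population: Population | str | None = None,
    domain: Domain | str | None = None,
) -> list[PolicyEvent]:
    """Events having at least one measure matching *all* given attributes."""
    direction = _coerce(direction, Direction, "direction")
    population = _coerce(population, Population, "population")
    domain = _coerce(domain, Domain, "domain")

    def match(m: PolicyMeasure) -> bool:
        return (
            (direction is None or m.direction == direction)
            and (population is None or m.population == population)
            and (domain is None or m.domain == domain)
        )

    return [ev for ev in events if any(match(m) for m in ev.measures)]


def timeline_schema() -> dict:
    """JSON schema of the nested timeline document."""
    event_schema = PolicyEvent.model_json_schema()
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "PolicyTimeline",
        "type": "object",
        "required": ["events"],
        "properties": {"events": {"type": "array", "items": event_schema}},
    }
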