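"""Bundled example data: the Lithuanian 2000-2019 policy study inputs.

Two small text files ship with the package:

* ``lithuania_economy.csv`` — annual disposable-income and alcohol-price
  indices (2010 = 100) for 2007-2019, as published by the national
  statistics office.
* ``lithuania_timeline.json`` — the 21 major alcohol-control policy
  events of 2001-2019 with curated measure attributes (see the
  ``curation_notes`` inside the file).
"""

from __future__ import annotations

from importlib import resources

from .economics import EconomicSeries, read_economy_csv
from .timeline import PolicyEvent, load_timeline

__all__ = ["load_lithuania_economy", "load_lithuania_timeline", "data_path"]

LITHUANIA_BASE_YEAR = 2010


def data_path(name: str):
    """Filesystem path of a bundled data file."""
    return resources.files("alcpolicy.data").joinpath(name)


def load_lithuania_economy() -> EconomicSeries:
    """Annual income and alcohol-price indices, Lithuania 2007-2019 (2010 = 100)."""
    with resources.as_file(data_path("lithuania_economy.csv")) as p:
        return read_economy_csv(p, base_year=LITHUANIA_BASE_YEAR)


def load_lithuania_timeline() -> list[PolicyEvent]:
    """The 21 major Lithuanian alcohol-control policy events, 2001-2019."""
    with resources.as_file(data_path("lithuania_timeline.json")) as p:
        return load_timeline(p)
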