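"""Registration-criteria eras of the child dental registry.

The registry has used three successive sets of registration criteria for
gingivitis, periodontitis and caries: 1972–1987, 1988–1999 and 2000 to the
present.  Every harmonization rule in this package is keyed on these
criteria eras.  (The registry's *datasets* split at 1988 and 1995 instead;
dataset-of-origin is metadata only and never drives scoring logic.)
"""

from __future__ import annotations

import datetime as dt
from enum import Enum

__all__ = ["CriteriaEra", "era_of", "REGISTRY_START_YEAR"]

REGISTRY_START_YEAR = 1972


class CriteriaEra(Enum):
    """One of the three registration-criteria periods."""

    ERA1 = "era1"  # 1972–1987
    ERA2 = "era2"  # 1988–1999
    ERA3 = "era3"  # 2000–present

    @property
    def year_range(self) -> tuple[int, int | None]:
        """(first, last) calendar year; last is ``None`` for the open era."""
        return {
            CriteriaEra.ERA1: (1972, 1987),
            CriteriaEra.ERA2: (1988, 1999),
            CriteriaEra.ERA3: (2000, None),
        }[self]

    @classmethod
    def of_year(cls, year: int) -> "CriteriaEra":
        if year < REGISTRY_START_YEAR:
            raise ValueError(
                f"visit year {year} predates the registry ({REGISTRY_START_YEAR})"
            )
        if year <= 1987:
            return cls.ERA1
        if year <= 1999:
            return cls.ERA2
        return cls.ERA3


def era_of(visit_date: dt.date) -> CriteriaEra:
    """Map a visit date onto its registration-criteria era.

    Total and monotone in the visit year; years before 1972 are rejected
    because no registration criteria existed for them.
    """
    return CriteriaEra.of_year(visit_date.year)
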