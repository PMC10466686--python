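"""Domain records: persons and visit-level registrations.

A :class:`VisitRecord` is one dental examination.  Disease codes are kept
as strings exactly as they appear on the registration form; a blank field
on the form is represented by *absence* from the mapping, so an empty
mapping means "nothing registered".  Code alphabets are closed per era —
anything outside them is a parse/contract error, never silently coerced.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping

from .eras import CriteriaEra, era_of
from .teeth import SURFACES, index_teeth, is_permanent, is_valid_fdi

__all__ = [
    "CARIES_CODES",
    "ERA1_POCKET_FLAGS",
    "GINGIVA_ALPHABETS",
    "POCKET_ALPHABETS",
    "Person",
    "VisitRecord",
    "persons_by_id",
]

#: Per-era gingiva code alphabets (the blank field is encoded by absence).
#: 1972–1987 grades each index tooth 0–3; 1988–1999 uses 1 (no bleeding),
#: 2 (bleeding on probing) and X (missing registration tooth); from 2000 a
#: single bleeding code 1 remains, plus X.
GINGIVA_ALPHABETS: dict[CriteriaEra, frozenset[str]] = {
    CriteriaEra.ERA1: frozenset({"0", "1", "2", "3"}),
    CriteriaEra.ERA2: frozenset({"1", "2", "X"}),
    CriteriaEra.ERA3: frozenset({"1", "X"}),
}

#: Per-tooth pocket code alphabets for 1988 on.  1988–1999: 4 (pockets
#: > 4 mm), 5 (pockets > 4 mm with attachment loss), X (missing tooth);
#: 2000 on: 0/1 indicator plus X.  1972–1987 has no per-tooth pocket codes,
#: only the record-level pathological-pockets flag.
POCKET_ALPHABETS: dict[CriteriaEra, frozenset[str]] = {
    CriteriaEra.ERA2: frozenset({"4", "5", "X"}),
    CriteriaEra.ERA3: frozenset({"0", "1", "X"}),
}

#: 1972–1987 record-level pathological-pockets flag: X = registered, blank
#: (absent) = either healthy or never examined.
ERA1_POCKET_FLAGS = frozenset({"X"})

#: Surface caries code alphabet (0 = sound; meanings of 1/2/4/5/6 follow
#: the registry's surface-code list and are treated as opaque labels here).
CARIES_CODES = frozenset({0, 1, 2, 4, 5, 6})


@dataclass(frozen=True)
class Person:
    """One individual in the person table."""

    person_id: str
    sex: str  # "F" or "M"
    birth_date: dt.date
    death_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.death_date is not None and self.death_date < self.birth_date:
            raise ValueError(
                f"person {self.person_id}: death date {self.death_date} "
                f"precedes birth date {self.birth_date}"
            )


def persons_by_id(persons) -> dict[str, Person]:
    """Index a person table by person_id, rejecting duplicate ids."""
    if isinstance(persons, Mapping):
        return dict(persons)
    out: dict[str, Person] = {}
    for p in persons:
        if p.person_id in out:
            raise ValueError(f"duplicate person_id {p.person_id!r} in person table")
        out[p.person_id] = p
    return out


@dataclass
class VisitRecord:
    """One dental examination, coded under the criteria era of its date.

    ``gingiva_codes`` and ``pocket_codes`` map FDI index-tooth → code
    string; ``surface_codes`` maps (FDI tooth, surface letter) → caries
    code.  ``pocket_flag`` is the 1972–1987 record-level pathological-
    pockets field ("X" or None).  ``extras`` carries unknown file columns
    through read/write untouched.
    """

    person_id: str
    visit_date: dt.date
    report_year: int | None = None
    municipality_code: int | None = None
    era: CriteriaEra | None = None
    gingiva_codes: dict[int, str] = field(default_factory=dict)
    pocket_codes: dict[int, str] = field(default_factory=dict)
    pocket_flag: str | None = None
    surface_codes: dict[tuple[int, str], int] = field(default_factory=dict)
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.era is None:
            self.era = era_of(self.visit_date)

    def copy(self) -> "VisitRecord":
        return replace(
            self,
            gingiva_codes=dict(self.gingiva_codes),
            pocket_codes=dict(self.pocket_codes),
            surface_codes=dict(self.surface_codes),
            extras=dict(self.extras),
        )

    def validation_errors(self) -> list[str]:
        """Contract checks: codes within the era's alphabets, gingiva and
        pocket keys within the era's index teeth, surfaces valid."""
        era = self.era
        problems: list[str] = []
        if era_of(self.visit_date) is not era:
            problems.append(
                f"era {era.value} inconsistent with visit date {self.visit_date}"
            )
        ging_alpha = GINGIVA_ALPHABETS[era]
        allowed = (
            index_teeth(era, "temporary") | index_teeth(era, "permanent")
        )
        for tooth, code in self.gingiva_codes.items():
            if tooth not in allowed:
                problems.append(f"gingiva tooth {tooth} is not an index tooth of {era.value}")
            if code not in ging_alpha:
                problems.append(f"gingiva code {code!r} outside {era.value} alphabet")
        if era is CriteriaEra.ERA1:
            if self.pocket_codes:
                problems.append("1972–1987 records carry no per-tooth pocket codes")
            if self.pocket_flag is not None and self.pocket_flag not in ERA1_POCKET_FLAGS:
                problems.append(f"pocket flag {self.pocket_flag!r} must be 'X' or blank")
            if len(self.gingiva_codes) > 4:
                problems.append(
                    "1972–1987 gingivitis index is defined over four index teeth; "
                    f"{len(self.gingiva_codes)} teeth graded"
                )
        else:
            if self.pocket_flag is not None:
                problems.append("record-level pocket flag exists only in 1972–1987")
            pock_alpha = POCKET_ALPHABETS[era]
            for tooth, code in self.pocket_codes.items():
                if tooth not in allowed:
                    problems.append(
                        f"pocket tooth {tooth} is not an index tooth of {era.value}"
                    )
                if code not in pock_alpha:
                    problems.append(f"pocket code {code!r} outside {era.value} alphabet")
        for (tooth, surface), code in self.surface_codes.items():
            if not is_valid_fdi(tooth):
                problems.append(f"invalid FDI tooth {tooth} in surface codes")
            if surface not in SURFACES:
                problems.append(f"invalid surface {surface!r} (expected one of {SURFACES})")
            if code not in CARIES_CODES:
                problems.append(f"caries code {code!r} outside alphabet {sorted(CARIES_CODES)}")
        return problems

    def identity_key(self):
        """Hashable full-field key; two records are exact duplicates iff
        their keys are equal."""
        return (
            self.person_id,
            self.visit_date,
            self.report_year,
            self.municipality_code,
            self.era,
            tuple(sorted(self.gingiva_codes.items())),
            tuple(sorted(self.pocket_codes.items())),
            self.pocket_flag,
            tuple(sorted(self.surface_codes.items())),
            tuple(sorted(self.extras.items())),
        )
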