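"""Era-comparable aggregate variables for gingivitis, periodontitis and DMF.

The three criteria eras registered the core diseases differently, so raw
codes are not comparable across eras.  This module computes the aggregate
variables that are:

* **Gingivitis score** — 1972–1987: the gingivitis index, the sum of four
  index-tooth grades (0–3 each, range 0–12); 1988–1999: the number of the
  twelve index teeth coded 2 (bleeding on probing); 2000 on: the number
  coded 1.  The harmonized flag is positive at index ≥ 9 for 1972–1987
  (which forces at least one severely inflamed tooth) and at ≥ 6 of 12
  teeth thereafter.
* **Pocket count / periodontitis** — 1972–1987: the record-level
  pathological-pockets flag (X registered / NA); 1988–1999: the number of
  index teeth coded 5 (code 4, pockets without attachment loss, does NOT
  count); 2000 on: the sum of the twelve per-tooth indicators (X, a
  missing registration tooth, contributes 0).  The flag is positive on X
  for 1972–1987 and at a count ≥ 6 thereafter.
* **DMF-S** — decayed/missing/filled surfaces: the count of surfaces with
  caries codes 1, 2, 4 or 6, split into temporary (dmf_s) and permanent
  (DMF_S) dentition.  The registry's own 1988+ temporary-dentition
  variable additionally counts code 5; the ``scor_provided`` variant
  reproduces that, while the default ``international`` variant omits code
  5 everywhere for comparability with DMF indices elsewhere.

Blank registrations score 0 and flag negative, matching the aggregate
definitions — but for 1988+ gingivitis and pre-2000 pockets a fully blank
form is indistinguishable from "not examined", so each aggregate carries
an *unregistered* indicator (all relevant fields blank) that analysts can
stratify on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .eras import CriteriaEra
from .records import (
    CARIES_CODES,
    GINGIVA_ALPHABETS,
    POCKET_ALPHABETS,
    Person,
    VisitRecord,
    persons_by_id,
)
from .teeth import Dentition, is_permanent, is_primary

__all__ = [
    "AggregateScores",
    "CariesVariant",
    "GINGIVITIS_THRESHOLDS",
    "POCKET_THRESHOLD",
    "aggregate_visit",
    "aggregates_frame",
    "dmf_surfaces",
    "gingivitis_flag",
    "gingivitis_score",
    "periodontitis_flag",
    "pocket_count",
]

CariesVariant = Literal["international", "scor_provided"]

#: Harmonized gingivitis cut-offs: index ≥ 9 under the 1972–1987 criteria,
#: at least 6 of 12 index teeth positive from 1988 on.
GINGIVITIS_THRESHOLDS: dict[CriteriaEra, int] = {
    CriteriaEra.ERA1: 9,
    CriteriaEra.ERA2: 6,
    CriteriaEra.ERA3: 6,
}

#: Harmonized pocket-count cut-off for 1988 on.
POCKET_THRESHOLD = 6

#: Caries codes counted by the international DMF definition.
DMF_CODES = frozenset({1, 2, 4, 6})


def _check_alphabet(era: CriteriaEra, codes: Mapping[int, str], alphabets) -> None:
    bad = {c for c in codes.values() if c not in alphabets[era]}
    if bad:
        raise ValueError(f"codes {sorted(bad)} outside the {era.value} alphabet")


def gingivitis_score(era: CriteriaEra, gingiva_codes: Mapping[int, str]) -> int:
    """Harmonized gingivitis score on the 0–12 scale (blank teeth score 0)."""
    _check_alphabet(era, gingiva_codes, GINGIVA_ALPHABETS)
    if era is CriteriaEra.ERA1:
        if len(gingiva_codes) > 4:
            raise ValueError("the 1972–1987 index grades at most four index teeth")
        return sum(int(c) for c in gingiva_codes.values())
    if era is CriteriaEra.ERA2:
        return sum(1 for c in gingiva_codes.values() if c == "2")
    return sum(1 for c in gingiva_codes.values() if c == "1")


def gingivitis_flag(era: CriteriaEra, score: int) -> bool:
    """Harmonized gingivitis classification from the era's score."""
    if not 0 <= score <= 12:
        raise ValueError(f"gingivitis score {score} outside 0–12")
    return score >= GINGIVITIS_THRESHOLDS[era]


def pocket_count(
    era: CriteriaEra,
    pocket_codes: Mapping[int, str],
    pocket_flag: str | None = None,
) -> int | str:
    """Pocket registration count (1988 on) or the 1972–1987 flag.

    1972–1987 returns ``"X"``/``"NA"`` from the record-level pathological-
    pockets field; an X on any index tooth is accepted as an equivalent
    input.  1988–1999 counts teeth coded 5 only; 2000 on sums the twelve
    0/1 indicators, with X (missing registration tooth) contributing 0.
    """
    if era is CriteriaEra.ERA1:
        if pocket_flag not in (None, "", "X"):
            raise ValueError(f"1972–1987 pocket flag must be X or blank, got {pocket_flag!r}")
        if pocket_flag == "X" or any(c == "X" for c in pocket_codes.values()):
            return "X"
        return "NA"
    _check_alphabet(era, pocket_codes, POCKET_ALPHABETS)
    if era is CriteriaEra.ERA2:
        return sum(1 for c in pocket_codes.values() if c == "5")
    return sum(1 for c in pocket_codes.values() if c == "1")


def periodontitis_flag(era: CriteriaEra, count: int | str) -> bool:
    """Harmonized periodontitis classification.

    1972–1987: positive iff the pathological-pockets flag is X (a single
    registered tooth sufficed, the registration being non-mandatory then);
    1988 on: positive at a pocket count of at least 6 of 12 teeth.
    """
    if era is CriteriaEra.ERA1:
        if count not in ("X", "NA"):
            raise ValueError(f"1972–1987 pocket value must be 'X' or 'NA', got {count!r}")
        return count == "X"
    if not isinstance(count, int) or not 0 <= count <= 12:
        raise ValueError(f"pocket count {count!r} outside 0–12")
    return count >= POCKET_THRESHOLD


def dmf_surfaces(
    surface_codes: Mapping[tuple[int, str], int],
    dentition: Dentition,
    era: CriteriaEra,
    variant: CariesVariant = "international",
) -> int:
    """Decayed/missing/filled surface count for one dentition.

    Counts surfaces coded 1, 2, 4 or 6.  Under ``scor_provided`` the
    registry's own 1988+ temporary-dentition definition is reproduced,
    which additionally counts code 5; the default omits code 5 throughout
    for international comparability.
    """
    if variant not in ("international", "scor_provided"):
        raise ValueError(f"unknown caries variant {variant!r}")
    bad = {c for c in surface_codes.values() if c not in CARIES_CODES}
    if bad:
        raise ValueError(f"caries codes {sorted(bad)} outside alphabet")
    in_dentition = is_primary if dentition == "temporary" else is_permanent
    qualifying = set(DMF_CODES)
    if (
        variant == "scor_provided"
        and dentition == "temporary"
        and era in (CriteriaEra.ERA2, CriteriaEra.ERA3)
    ):
        qualifying.add(5)
    return sum(
        1
        for (tooth, _surface), code in surface_codes.items()
        if in_dentition(tooth) and code in qualifying
    )


@dataclass(frozen=True)
class AggregateScores:
    """Harmonized per-visit aggregates for the three core diseases."""

    era: CriteriaEra
    gingivitis_score: int
    gingivitis_flag: bool
    pocket_count: int | str
    periodontitis_flag: bool
    dmf_s: int
    DMF_S: int
    dmf_total: int
    caries_variant: CariesVariant
    #: no gingiva field registered at all (1988 on: healthy vs not examined
    #: cannot be distinguished)
    gingiva_unregistered: bool
    #: no pocket field registered at all (pre-2000: same ambiguity)
    pockets_unregistered: bool
    #: diagnostic only — 1988–1999 teeth coded 4 (pockets without
    #: attachment loss); never contributes to any aggregate
    era2_code4_count: int | None = None


def aggregate_visit(
    record: VisitRecord, variant: CariesVariant = "international"
) -> AggregateScores:
    """Compute all harmonized aggregates for one (cleaned) visit record."""
    era = record.era
    score = gingivitis_score(era, record.gingiva_codes)
    count = pocket_count(era, record.pocket_codes, record.pocket_flag)
    dmf_temp = dmf_surfaces(record.surface_codes, "temporary", era, variant)
    dmf_perm = dmf_surfaces(record.surface_codes, "permanent", era, variant)
    if era is CriteriaEra.ERA1:
        pockets_unregistered = count == "NA"
        code4 = None
    else:
        pockets_unregistered = not record.pocket_codes
        code4 = (
            sum(1 for c in record.pocket_codes.values() if c == "4")
            if era is CriteriaEra.ERA2
            else None
        )
    return AggregateScores(
        era=era,
        gingivitis_score=score,
        gingivitis_flag=gingivitis_flag(era, score),
        pocket_count=count,
        periodontitis_flag=periodontitis_flag(era, count),
        dmf_s=dmf_temp,
        DMF_S=dmf_perm,
        dmf_total=dmf_temp + dmf_perm,
        caries_variant=variant,
        gingiva_unregistered=not record.gingiva_codes,
        pockets_unregistered=pockets_unregistered,
        era2_code4_count=code4,
    )


def aggregates_frame(
    records: Iterable[VisitRecord],
    persons: Iterable[Person] | Mapping[str, Person] | None = None,
    variant: CariesVariant = "international",
) -> pd.DataFrame:
    """Tidy per-visit aggregate table for the summary operations.

    One row per record: identifiers, era, visit/report year, the
    harmonized scores and flags, and — when a person table is supplied —
    sex, birth year and rounded age at visit.
    """
    from .cleaning import rounded_age  # late import to avoid a cycle

    lookup = persons_by_id(persons) if persons is not None else None
    rows = []
    for r in records:
        agg = aggregate_visit(r, variant)
        row = {
            "person_id": r.person_id,
            "visit_date": r.visit_date,
            "visit_year": r.visit_date.year,
            "report_year": r.report_year,
            "era": r.era.value,
            "gingivitis_score": agg.gingivitis_score,
            "gingivitis_flag": agg.gingivitis_flag,
            "pocket_count": agg.pocket_count,
            "periodontitis_flag": agg.periodontitis_flag,
            "dmf_s": agg.dmf_s,
            "DMF_S": agg.DMF_S,
            "dmf_total": agg.dmf_total,
            "gingiva_unregistered": agg.gingiva_unregistered,
            "pockets_unregistered": agg.pockets_unregistered,
            "era2_code4_count": agg.era2_code4_count,
        }
        if lookup is not None:
            person = lookup[r.person_id]
            row["sex"] = person.sex
            row["birth_year"] = person.birth_date.year
            row["age"] = rounded_age(person.birth_date, r.visit_date)
        rows.append(row)
    return pd.DataFrame(rows)
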