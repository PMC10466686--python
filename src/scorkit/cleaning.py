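"""Record cleaning: deduplication, fault removal, one entry per year of age.

The pipeline applies three stages in a fixed, documented order (the order
affects the per-rule counts):

1. **Duplicates** — exact-duplicate rows (every field equal) are reduced
   to their first occurrence.
2. **Faulty records** — visits after the person's date of death, and
   visits at an exact age outside the open interval 0 < age < 19 years
   (the eligibility window of the child oral healthcare scheme).
3. **Age restriction** — per person and integer year of age (0–18) only
   the earliest-dated entry is kept; a same-date tie keeps the first row
   in stable input order.

Exact age is (visit − birth) in days divided by 365.25.  The integer age
used by the restriction rounds half *down* by default (7.5 → 7), so an
exact half-year never inflates the age past a boundary; conventional
floor rounding is available via the ``rounding`` switch.

Every stage reports how many rows it removed; the :class:`CleaningReport`
conserves rows (input = output + all removals) and the full pipeline is
idempotent.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .records import Person, VisitRecord, persons_by_id

__all__ = [
    "CleaningReport",
    "clean_pipeline",
    "drop_duplicates",
    "drop_faulty",
    "exact_age_years",
    "restrict_one_per_age",
    "rounded_age",
]

DAYS_PER_YEAR = 365.25

Rounding = Literal["round", "floor"]


def exact_age_years(birth_date: dt.date, visit_date: dt.date) -> float:
    """Age at visit in exact (fractional) years."""
    return (visit_date - birth_date).days / DAYS_PER_YEAR


def rounded_age(
    birth_date: dt.date, visit_date: dt.date, rounding: Rounding = "round"
) -> int:
    """Integer age at visit: round-half-down by default, or floor."""
    age = exact_age_years(birth_date, visit_date)
    if rounding == "floor":
        return math.floor(age)
    if rounding == "round":
        return math.ceil(age - 0.5)
    raise ValueError(f"unknown rounding {rounding!r}")


def eligible_age(age_years: float) -> bool:
    """The care-eligibility predicate 0 < age < 19 (exact years, open)."""
    return 0.0 < age_years < 19.0


@dataclass
class CleaningReport:
    """Auditable per-rule removal counts for one pipeline run."""

    n_input: int
    n_duplicates_removed: int
    n_death_removed: int
    n_age_removed: int
    n_age_restriction_removed: int
    n_output: int
    n_unresolved_person: int = 0

    @property
    def n_faulty_removed(self) -> int:
        return self.n_death_removed + self.n_age_removed

    def conserves_rows(self) -> bool:
        return self.n_input == (
            self.n_output
            + self.n_duplicates_removed
            + self.n_faulty_removed
            + self.n_age_restriction_removed
            + self.n_unresolved_person
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_faulty_removed": self.n_faulty_removed,
            "n_death_removed": self.n_death_removed,
            "n_age_removed": self.n_age_removed,
            "n_age_restriction_removed": self.n_age_restriction_removed,
            "n_unresolved_person": self.n_unresolved_person,
            "n_output": self.n_output,
        }


def drop_duplicates(records: Iterable[VisitRecord]) -> tuple[list[VisitRecord], int]:
    """Remove exact-duplicate rows, keeping the first occurrence of each."""
    seen = set()
    kept: list[VisitRecord] = []
    removed = 0
    for r in records:
        key = r.identity_key()
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(r)
    return kept, removed


def drop_faulty(
    records: Iterable[VisitRecord],
    persons: Iterable[Person] | Mapping[str, Person],
) -> tuple[list[VisitRecord], dict[str, int], list[VisitRecord]]:
    """Remove faulty rows; returns (kept, counts by rule, unresolved rows).

    Rules, checked in order: visit after the person's death date, then
    exact age outside 0 < age < 19.  A row violating both is counted under
    the death rule.  Rows whose person_id does not resolve in the person
    table are routed to the unresolved list, never silently dropped.
    """
    lookup = persons_by_id(persons)
    kept: list[VisitRecord] = []
    unresolved: list[VisitRecord] = []
    counts = {"death_before_visit": 0, "age_out_of_range": 0}
    for r in records:
        person = lookup.get(r.person_id)
        if person is None:
            unresolved.append(r)
            continue
        if person.death_date is not None and person.death_date < r.visit_date:
            counts["death_before_visit"] += 1
            continue
        if not eligible_age(exact_age_years(person.birth_date, r.visit_date)):
            counts["age_out_of_range"] += 1
            continue
        kept.append(r)
    return kept, counts, unresolved


def restrict_one_per_age(
    records: Iterable[VisitRecord],
    persons: Iterable[Person] | Mapping[str, Person],
    rounding: Rounding = "round",
) -> tuple[list[VisitRecord], int]:
    """Keep, per person and integer age, only the earliest-dated entry.

    Ties on the visit date keep the first row in stable input order.
    Assumes faulty rows are already removed (every person_id resolves).
    """
    lookup = persons_by_id(persons)
    best: dict[tuple[str, int], tuple[dt.date, int]] = {}
    rows = list(records)
    for i, r in enumerate(rows):
        age = rounded_age(lookup[r.person_id].birth_date, r.visit_date, rounding)
        key = (r.person_id, age)
        if key not in best or r.visit_date < best[key][0]:
            best[key] = (r.visit_date, i)
    keep_idx = {i for (_, i) in best.values()}
    kept = [r for i, r in enumerate(rows) if i in keep_idx]
    return kept, len(rows) - len(kept)


def clean_pipeline(
    records: Iterable[VisitRecord],
    persons: Iterable[Person] | Mapping[str, Person],
    rounding: Rounding = "round",
) -> tuple[list[VisitRecord], CleaningReport, list[VisitRecord]]:
    """Full cleaning pipeline: duplicates → faulty → one entry per age.

    Returns (cleaned records, report, unresolved-person rows).  The report
    conserves rows and the pipeline is idempotent: applied to its own
    output it removes nothing.
    """
    rows = list(records)
    deduped, n_dup = drop_duplicates(rows)
    valid, fault_counts, unresolved = drop_faulty(deduped, persons)
    restricted, n_restricted = restrict_one_per_age(valid, persons, rounding)
    report = CleaningReport(
        n_input=len(rows),
        n_duplicates_removed=n_dup,
        n_death_removed=fault_counts["death_before_visit"],
        n_age_removed=fault_counts["age_out_of_range"],
        n_age_restriction_removed=n_restricted,
        n_unresolved_person=len(unresolved),
        n_output=len(restricted),
    )
    assert report.conserves_rows()
    return restricted, report, unresolved
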