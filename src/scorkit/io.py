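"""Delimited-text readers and writers for visit and person tables.

Each criteria era has its own column dialect, mirroring how the registry's
registration form changed over time:

* ``era1`` — gingiva grade columns for the eight possible 1972–1987 index
  teeth (``ging_52 … ging_85`` primary, ``ging_12 … ging_46`` permanent; at
  most four graded on one visit) plus the record-level
  ``patologiske_pocher`` flag.
* ``era2`` / ``era3`` — gingiva and per-tooth pocket columns for the twelve
  permanent index teeth (``ging_11 … ging_46``, ``poch_11 … poch_46``), with
  era-specific code alphabets.

All dialects share ``person_id``, ``visit_date`` (ISO 8601),
``report_year``, ``municipality_code`` and a packed ``caries`` column of
semicolon-separated ``<FDI><surface>:<code>`` tokens (e.g. ``16O:1;55M:4``;
sound surfaces are simply absent).  Unknown columns round-trip untouched
as record extras.  The delimiter is a comma for ``.csv`` and a tab for
``.tsv``/``.tab``/``.txt``.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .eras import CriteriaEra
from .records import Person, VisitRecord

__all__ = [
    "DIALECT_COLUMNS",
    "ParseError",
    "RowError",
    "read_persons",
    "read_visits",
    "write_persons",
    "write_visits",
]

_ERA1_GING_SLOTS = (52, 55, 82, 85, 12, 16, 42, 46)
_ERA23_SLOTS = (11, 12, 16, 21, 22, 26, 31, 32, 36, 41, 42, 46)

_COMMON = ("person_id", "visit_date", "report_year", "municipality_code")

DIALECT_COLUMNS: dict[CriteriaEra, tuple[str, ...]] = {
    CriteriaEra.ERA1: _COMMON
    + tuple(f"ging_{t}" for t in _ERA1_GING_SLOTS)
    + ("patologiske_pocher", "caries"),
    CriteriaEra.ERA2: _COMMON
    + tuple(f"ging_{t}" for t in _ERA23_SLOTS)
    + tuple(f"poch_{t}" for t in _ERA23_SLOTS)
    + ("caries",),
    CriteriaEra.ERA3: _COMMON
    + tuple(f"ging_{t}" for t in _ERA23_SLOTS)
    + tuple(f"poch_{t}" for t in _ERA23_SLOTS)
    + ("caries",),
}

_CARIES_TOKEN = re.compile(r"^(\d{2})([MDBLO]):(\d)$")


@dataclass(frozen=True)
class RowError:
    """One rejected input row: 0-based data-row index, offending column
    (when attributable) and a message."""

    row: int
    column: str | None
    message: str


class ParseError(ValueError):
    """Raised in fail-fast mode on the first invalid row."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        first = errors[0]
        where = f"row {first.row}" + (f", column {first.column}" if first.column else "")
        super().__init__(f"{where}: {first.message}")


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _pack_caries(surface_codes: dict[tuple[int, str], int]) -> str:
    return ";".join(
        f"{tooth}{surface}:{code}"
        for (tooth, surface), code in sorted(surface_codes.items())
    )


def _unpack_caries(cell: str) -> dict[tuple[int, str], int]:
    out: dict[tuple[int, str], int] = {}
    if not cell:
        return out
    for token in cell.split(";"):
        m = _CARIES_TOKEN.match(token.strip())
        if m is None:
            raise ValueError(f"malformed caries token {token!r}")
        tooth, surface, code = int(m.group(1)), m.group(2), int(m.group(3))
        out[(tooth, surface)] = code
    return out


def write_visits(
    records: Iterable[VisitRecord], path: str | Path, dialect: CriteriaEra
) -> None:
    """Write visit records in the given era dialect.

    Every record must belong to the dialect's era; extras are appended as
    additional columns (sorted by name, union over all records).
    """
    path = Path(path)
    records = list(records)
    for r in records:
        if r.era is not dialect:
            raise ValueError(
                f"record dated {r.visit_date} is {r.era.value}, not {dialect.value}"
            )
    extra_cols = sorted({k for r in records for k in r.extras})
    columns = DIALECT_COLUMNS[dialect] + tuple(extra_cols)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path))
        writer.writerow(columns)
        for r in records:
            row = {
                "person_id": r.person_id,
                "visit_date": r.visit_date.isoformat(),
                "report_year": "" if r.report_year is None else str(r.report_year),
                "municipality_code": ""
                if r.municipality_code is None
                else str(r.municipality_code),
                "caries": _pack_caries(r.surface_codes),
            }
            for tooth, code in r.gingiva_codes.items():
                row[f"ging_{tooth}"] = code
            if dialect is CriteriaEra.ERA1:
                row["patologiske_pocher"] = r.pocket_flag or ""
            else:
                for tooth, code in r.pocket_codes.items():
                    row[f"poch_{tooth}"] = code
            row.update(r.extras)
            writer.writerow([row.get(c, "") for c in columns])


def read_visits(
    path: str | Path, dialect: CriteriaEra, fail_fast: bool = False
) -> tuple[list[VisitRecord], list[RowError]]:
    """Read a visit table in the given era dialect.

    Returns (records, row errors).  Invalid rows are excluded from the
    record list and reported with their 0-based data-row index and, where
    attributable, the offending column.  With ``fail_fast`` the first
    invalid row raises :class:`ParseError` instead.  A write/read round
    trip is lossless on valid records.
    """
    path = Path(path)
    expected = DIALECT_COLUMNS[dialect]
    records: list[VisitRecord] = []
    errors: list[RowError] = []

    def report(err: RowError) -> None:
        if fail_fast:
            raise ParseError([err])
        errors.append(err)

    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=_delimiter(path))
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row") from None
        missing = [c for c in expected if c not in header]
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {missing}")
        extra_cols = [c for c in header if c not in expected]
        for i, cells in enumerate(reader):
            cells += [""] * (len(header) - len(cells))
            row = dict(zip(header, cells))
            try:
                record = _parse_row(row, dialect, extra_cols)
            except _CellError as exc:
                report(RowError(i, exc.column, str(exc)))
                continue
            problems = record.validation_errors()
            if problems:
                report(RowError(i, None, "; ".join(problems)))
                continue
            records.append(record)
    return records, errors


class _CellError(ValueError):
    def __init__(self, column: str, message: str):
        self.column = column
        super().__init__(message)


def _parse_row(
    row: dict[str, str], dialect: CriteriaEra, extra_cols: list[str]
) -> VisitRecord:
    if not row["person_id"]:
        raise _CellError("person_id", "person_id is empty")
    try:
        visit_date = dt.date.fromisoformat(row["visit_date"])
    except ValueError:
        raise _CellError("visit_date", f"unparseable date {row['visit_date']!r}")
    try:
        era = CriteriaEra.of_year(visit_date.year)
    except ValueError as exc:
        raise _CellError("visit_date", str(exc))
    if era is not dialect:
        raise _CellError(
            "visit_date", f"date {visit_date} belongs to {era.value}, not {dialect.value}"
        )

    def opt_int(column: str) -> int | None:
        cell = row.get(column, "").strip()
        if not cell:
            return None
        try:
            return int(cell)
        except ValueError:
            raise _CellError(column, f"not an integer: {cell!r}")

    gingiva: dict[int, str] = {}
    slots = _ERA1_GING_SLOTS if dialect is CriteriaEra.ERA1 else _ERA23_SLOTS
    for tooth in slots:
        cell = row.get(f"ging_{tooth}", "").strip()
        if cell:
            gingiva[tooth] = cell
    pockets: dict[int, str] = {}
    pocket_flag: str | None = None
    if dialect is CriteriaEra.ERA1:
        cell = row.get("patologiske_pocher", "").strip()
        pocket_flag = cell or None
    else:
        for tooth in _ERA23_SLOTS:
            cell = row.get(f"poch_{tooth}", "").strip()
            if cell:
                pockets[tooth] = cell
    try:
        surfaces = _unpack_caries(row.get("caries", "").strip())
    except ValueError as exc:
        raise _CellError("caries", str(exc))
    return VisitRecord(
        person_id=row["person_id"],
        visit_date=visit_date,
        report_year=opt_int("report_year"),
        municipality_code=opt_int("municipality_code"),
        era=era,
        gingiva_codes=gingiva,
        pocket_codes=pockets,
        pocket_flag=pocket_flag,
        surface_codes=surfaces,
        extras={c: row.get(c, "") for c in extra_cols},
    )


_PERSON_COLUMNS = ("person_id", "sex", "birth_date", "death_date")


def write_persons(persons: Iterable[Person], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path))
        writer.writerow(_PERSON_COLUMNS)
        for p in persons:
            writer.writerow(
                [
                    p.person_id,
                    p.sex,
                    p.birth_date.isoformat(),
                    p.death_date.isoformat() if p.death_date else "",
                ]
            )


def read_persons(path: str | Path) -> list[Person]:
    path = Path(path)
    out: list[Person] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(path))
        missing = [c for c in _PERSON_COLUMNS[:3] if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {missing}")
        for i, row in enumerate(reader):
            pid = row["person_id"]
            if pid in seen:
                raise ValueError(f"{path}: duplicate person_id {pid!r} at row {i}")
            seen.add(pid)
            death = (row.get("death_date") or "").strip()
            out.append(
                Person(
                    person_id=pid,
                    sex=row["sex"].strip(),
                    birth_date=dt.date.fromisoformat(row["birth_date"]),
                    death_date=dt.date.fromisoformat(death) if death else None,
                )
            )
    return out
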