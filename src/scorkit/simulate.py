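"""Synthetic registry generator with planted truth and injected faults.

The real registry is access-restricted, so every downstream stage of this
package is exercised on a simulated stand-in that emulates its structure:
per-visit index-tooth gingiva and pocket codes under each era's coding
scheme, per-surface caries codes for both dentitions, age-dependent latent
disease, era-appropriate visit schedules (annual reporting before 1993;
mandatory ages 5/7/12/15 plus needs-based visits after), and injected
exact duplicates and faulty rows (death before visit, out-of-range ages).

The generator keeps a :class:`FaultLedger` of every planted fault and a
latent-state table of the planted per-(person, age) disease truth, which
serve as exact oracles for the cleaning and harmonization stages: with a
detection probability of 1 the harmonized flags reproduce the latent flags
visit by visit, and the cleaning report must match the ledger count for
count.

Latent disease is a per-age Bernoulli chain: each year the previous state
is carried with probability ``persistence`` and redrawn otherwise, with
the redraw probability adjusted so the *marginal* prevalence at every age
equals the configured prevalence curve exactly.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .eras import CriteriaEra, era_of
from .records import Person, VisitRecord
from .teeth import PERMANENT_FDI, PRIMARY_FDI, SURFACES, index_teeth

__all__ = [
    "FaultLedger",
    "LatentState",
    "SimulationConfig",
    "SimulationResult",
    "default_prevalence_curves",
    "default_visit_schedule",
    "emit_era_coding",
    "inject_faults",
    "simulate_cohort",
]

DISEASES = ("gingivitis", "periodontitis", "caries")

#: Calendar year from which reporting switched from annual to needs-based
#: with mandatory ages 5, 7, 12 and 15.
REGIME_CHANGE_YEAR = 1993
MANDATORY_AGES = frozenset({5, 7, 12, 15})

_DMF_EMIT_CODES = np.array([1, 2, 4, 6])
_PRIMARY_SURFACE_SPACE = [(t, s) for t in PRIMARY_FDI for s in SURFACES]
_PERMANENT_SURFACE_SPACE = [(t, s) for t in PERMANENT_FDI for s in SURFACES]


def default_visit_schedule() -> dict[str, dict]:
    """Per-age visit probabilities by reporting regime.

    Annual reporting (pre-1993) was mandatory for every age; needs-based
    reporting keeps high coverage at the mandatory ages and — as the
    registry's own visit-by-age profile shows — substantial attendance at
    all other ages too.
    """
    return {
        "annual": {"default": 0.95},
        "needs_based": {5: 0.95, 7: 0.95, 12: 0.95, 15: 0.95, "default": 0.55},
    }


def _gingivitis_curve(age: int, year: int) -> float:
    # ramps from 5% in early childhood to 30% at age 15 and above
    if age <= 4:
        return 0.05
    return min(0.05 + 0.025 * (age - 5), 0.30)


def _periodontitis_curve(age: int, year: int) -> float:
    # rare before adolescence, rising towards late teens
    if age < 10:
        return 0.002
    return 0.01 + 0.09 * min(age - 10, 8) / 8


def _caries_curve(age: int, year: int) -> float:
    # age-increasing caries risk with a secular decline reaching half the
    # 1972 level by 2021
    base = min(0.10 + 0.04 * age, 0.75)
    secular = 1.0 - 0.5 * min(max(year - 1972, 0), 49) / 49
    return base * secular


def default_prevalence_curves() -> dict[str, Callable[[int, int], float]]:
    """Latent prevalence as functions of (age, calendar year).

    No published numeric prevalence values exist to calibrate against,
    so these are order-of-magnitude defaults: gingivitis
    reaching 30% by age 15, periodontitis rare and adolescent-onset,
    caries age-increasing with a ~50% secular decline from 1972 to 2021.
    """
    return {
        "gingivitis": _gingivitis_curve,
        "periodontitis": _periodontitis_curve,
        "caries": _caries_curve,
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``ages`` are the visit ages simulated; the latent chain always runs
    over ages 0–18 so marginal prevalences are well defined at every age.
    Identical config + seed gives byte-identical output.
    """

    n_individuals: int = 100
    birth_year_range: tuple[int, int] = (1960, 2005)
    male_fraction: float = 0.512
    ages: tuple[int, ...] = tuple(range(19))
    visit_schedule: dict[str, dict] = field(default_factory=default_visit_schedule)
    prevalence_curves: Mapping[str, Callable[[int, int], float]] = field(
        default_factory=default_prevalence_curves
    )
    persistence: float = 0.7
    caries_intensity: Mapping[str, float] = field(
        default_factory=lambda: {"temporary": 3.0, "permanent": 4.0}
    )
    detection: float = 1.0
    code5_rate: float = 0.05
    reporting_shock: float | None = None
    shock_years: int = 2
    duplicate_rate: float = 0.0002
    faulty_death_rate: float = 0.0002
    faulty_age_rate: float = 0.0004
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be at least 1")
        y0, y1 = self.birth_year_range
        if y0 > y1:
            raise ValueError(f"empty birth year range {self.birth_year_range}")
        for name in (
            "male_fraction",
            "persistence",
            "detection",
            "code5_rate",
            "duplicate_rate",
            "faulty_death_rate",
            "faulty_age_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.duplicate_rate + self.faulty_death_rate + self.faulty_age_rate > 1.0:
            raise ValueError("fault-injection rates sum to more than 1 per row")
        if not self.ages or min(self.ages) < 0 or max(self.ages) > 18:
            raise ValueError("visit ages must lie within 0–18")
        for regime in ("annual", "needs_based"):
            sched = self.visit_schedule.get(regime)
            if sched is None or "default" not in sched:
                raise ValueError(f"visit_schedule[{regime!r}] needs a 'default' entry")
            for p in sched.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"visit probability {p} outside [0, 1]")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        """Build a config from a plain mapping (e.g. a parsed YAML file).

        Scalar fields and the visit schedule are supported; prevalence
        curves are callables and can only be replaced from Python.
        """
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        kwargs = dict(data)
        if "birth_year_range" in kwargs:
            kwargs["birth_year_range"] = tuple(kwargs["birth_year_range"])
        if "ages" in kwargs:
            kwargs["ages"] = tuple(kwargs["ages"])
        if "visit_schedule" in kwargs:
            sched = {}
            for regime, entries in kwargs["visit_schedule"].items():
                sched[regime] = {
                    (k if k == "default" else int(k)): float(v)
                    for k, v in entries.items()
                }
            kwargs["visit_schedule"] = sched
        return cls(**kwargs)


@dataclass(frozen=True)
class LatentState:
    """Planted truth for one (person, age): disease indicators and the
    number of carious surfaces per dentition."""

    age: int
    year: int
    gingivitis: bool
    periodontitis: bool
    caries: bool
    caries_temp: int
    caries_perm: int


@dataclass
class FaultLedger:
    """Ground truth of injected faults: row indices into the emitted
    record list, one list per fault class, mutually disjoint."""

    duplicate_rows: list[int] = field(default_factory=list)
    death_rows: list[int] = field(default_factory=list)
    age_rows: list[int] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.duplicate_rows or self.death_rows or self.age_rows)

    def as_dict(self) -> dict[str, list[int]]:
        return {
            "duplicate_rows": list(self.duplicate_rows),
            "death_rows": list(self.death_rows),
            "age_rows": list(self.age_rows),
        }


@dataclass
class SimulationResult:
    """Everything one simulation run produces."""

    persons: list[Person]
    records: list[VisitRecord]
    ledger: FaultLedger
    latent: pd.DataFrame  # person_id, age, year, flags, surface counts

    def write(self, out_dir: str | Path) -> None:
        """Emit the run as delimited text: person table, one visit file
        per era dialect, the fault ledger and the latent-state table."""
        from .io import write_persons, write_visits

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_persons(self.persons, out / "persons.csv")
        for era in CriteriaEra:
            write_visits(
                [r for r in self.records if r.era is era],
                out / f"visits_{era.value}.csv",
                era,
            )
        (out / "fault_ledger.json").write_text(
            json.dumps(self.ledger.as_dict(), indent=2) + "\n"
        )
        self.latent.to_csv(out / "latent_states.csv", index=False)


def _temporary_fraction(age: int) -> float:
    """Share of carious surfaces placed in the temporary dentition:
    all of it before age 6, a declining share through the mixed-dentition
    years, none after age 12."""
    if age < 6:
        return 1.0
    return float(np.clip((13 - age) / 8, 0.0, 1.0))


def _simulate_latent_chain(
    cfg: SimulationConfig, rng: np.random.Generator, birth_year: int
) -> list[LatentState]:
    curves = cfg.prevalence_curves
    rho = cfg.persistence
    states: list[LatentState] = []
    prev = {d: False for d in DISEASES}
    prev_p = {d: 0.0 for d in DISEASES}
    severity = 0
    for age in range(19):
        year = birth_year + age
        flags = {}
        for d in DISEASES:
            p = float(np.clip(curves[d](age, year), 0.0, 1.0))
            if age == 0 or rho == 0.0:
                flags[d] = bool(rng.random() < p)
            elif rng.random() < rho:
                flags[d] = prev[d]
            else:
                q = float(np.clip((p - rho * prev_p[d]) / (1.0 - rho), 0.0, 1.0))
                flags[d] = bool(rng.random() < q)
            prev[d] = flags[d]
            prev_p[d] = p
        f_temp = _temporary_fraction(age)
        if flags["caries"]:
            mean = (
                f_temp * cfg.caries_intensity["temporary"]
                + (1 - f_temp) * cfg.caries_intensity["permanent"]
            )
            if severity == 0:
                severity = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
            else:
                severity = severity + int(rng.poisson(0.5))
            severity = min(severity, 60)
        else:
            severity = 0
        n_temp = int(rng.binomial(severity, f_temp)) if severity else 0
        n_perm = severity - n_temp
        states.append(
            LatentState(
                age=age,
                year=year,
                gingivitis=flags["gingivitis"],
                periodontitis=flags["periodontitis"],
                caries=flags["caries"],
                caries_temp=n_temp,
                caries_perm=n_perm,
            )
        )
    return states


def emit_era_coding(
    latent_state: LatentState,
    era: CriteriaEra,
    rng: np.random.Generator,
    detection: float = 1.0,
    code5_rate: float = 0.05,
) -> tuple[dict[int, str], dict[int, str], str | None, dict[tuple[int, str], int]]:
    """Code one visit under an era's registration scheme.

    Returns (gingiva codes, pocket codes, era-1 pocket flag, surface
    codes).  A latently positive disease is coded above the harmonized
    threshold with probability ``detection`` and below it otherwise, so at
    detection 1 the harmonized flags reproduce the latent truth exactly.
    Undetected disease leaves the fields blank — as does health under the
    1988+ gingivitis and pre-2000 pocket schemes, reproducing the
    registry's inability to distinguish a healthy dentition from a
    registration never made.  The 1972–1987 gingivitis grades were
    mandatory and are always filled in (grades 0–2 when below threshold).
    Carious surfaces get codes from {1, 2, 4, 6}; caries-affected visits
    under the 1988+ schemes occasionally gain temporary-dentition code-5
    surfaces, which the registry's own temporary-dentition DMF counts but
    the international variant does not.
    """
    detect = lambda flag: bool(flag and rng.random() < detection)
    ging_pos = detect(latent_state.gingivitis)
    perio_pos = detect(latent_state.periodontitis)
    caries_pos = detect(latent_state.caries)

    gingiva: dict[int, str] = {}
    pockets: dict[int, str] = {}
    pocket_flag: str | None = None

    if era is CriteriaEra.ERA1:
        dentition = "temporary" if latent_state.age < 6 else "permanent"
        slots = sorted(index_teeth(era, dentition))
        if ging_pos:
            severe = int(rng.integers(len(slots)))
            for i, tooth in enumerate(slots):
                gingiva[tooth] = "3" if i == severe else str(rng.choice(["2", "3"]))
        else:
            for tooth in slots:
                gingiva[tooth] = str(rng.choice(["0", "1", "2"]))
        pocket_flag = "X" if perio_pos else None
    else:
        slots = sorted(index_teeth(era, "permanent"))
        if ging_pos:
            pos_code = "2" if era is CriteriaEra.ERA2 else "1"
            n_pos = 6 + int(rng.binomial(6, 0.4))
            pos_teeth = {int(t) for t in rng.choice(slots, size=n_pos, replace=False)}
            for tooth in slots:
                if tooth in pos_teeth:
                    gingiva[tooth] = pos_code
                elif era is CriteriaEra.ERA2 and rng.random() < 0.5:
                    gingiva[tooth] = "1"  # examined, no bleeding
                elif rng.random() < 0.02:
                    gingiva[tooth] = "X"

        if perio_pos:
            pock_pos_code = "5" if era is CriteriaEra.ERA2 else "1"
            n_pock = 6 + int(rng.binomial(6, 0.3))
            pock_teeth = {int(t) for t in rng.choice(slots, size=n_pock, replace=False)}
            for tooth in slots:
                if tooth in pock_teeth:
                    pockets[tooth] = pock_pos_code
                elif rng.random() < 0.02:
                    pockets[tooth] = "X"
                elif era is CriteriaEra.ERA2:
                    if rng.random() < 0.08:
                        pockets[tooth] = "4"  # pockets without attachment loss
                else:
                    pockets[tooth] = "0"

    surfaces: dict[tuple[int, str], int] = {}
    if caries_pos:
        n_temp = min(latent_state.caries_temp, len(_PRIMARY_SURFACE_SPACE))
        n_perm = min(latent_state.caries_perm, len(_PERMANENT_SURFACE_SPACE))
        if n_temp:
            picks = rng.choice(len(_PRIMARY_SURFACE_SPACE), size=n_temp, replace=False)
            for i in picks:
                surfaces[_PRIMARY_SURFACE_SPACE[i]] = int(rng.choice(_DMF_EMIT_CODES))
        if n_perm:
            picks = rng.choice(len(_PERMANENT_SURFACE_SPACE), size=n_perm, replace=False)
            for i in picks:
                surfaces[_PERMANENT_SURFACE_SPACE[i]] = int(rng.choice(_DMF_EMIT_CODES))
        if era is not CriteriaEra.ERA1 and rng.random() < code5_rate:
            free = [p for p in _PRIMARY_SURFACE_SPACE if p not in surfaces]
            picks = rng.choice(
                len(free), size=min(1 + int(rng.integers(2)), len(free)), replace=False
            )
            for i in picks:
                surfaces[free[i]] = 5
    return gingiva, pockets, pocket_flag, surfaces


def _report_year(visit_date: dt.date) -> int | None:
    """Administrative reporting year: school-year based through 1987
    (August onward reports to the next year), birth-year/calendar based
    1988–1999, and absent from 2000 on (year of visit is the proxy)."""
    year = visit_date.year
    if year >= 2000:
        return None
    if year <= 1987 and visit_date.month >= 8:
        return year + 1
    return year


_MUNICIPALITIES = (101, 147, 250, 461, 751)
_NONEXISTENT_MUNICIPALITY = 999


def simulate_cohort(config: SimulationConfig) -> SimulationResult:
    """Generate a cohort: persons, era-coded visit records, fault ledger
    and the planted latent-state table.

    Visits occur at the configured ages with the probability given by the
    schedule of the calendar-year regime the visit falls in; visit dates
    land 30–180 days after the birthday so the exact age stays inside the
    eligibility window and rounds to the planted age.  Visits that would
    predate the registry's 1972 start are not emitted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.birth_year_range
    visit_ages = set(config.ages)

    persons: list[Person] = []
    records: list[VisitRecord] = []
    latent_rows: list[dict] = []

    shock_windows: set[int] = set()
    if config.reporting_shock is not None:
        for boundary in (1988, 2000):
            shock_windows.update(range(boundary, boundary + config.shock_years))

    for i in range(config.n_individuals):
        birth_year = int(rng.integers(y0, y1 + 1))
        birth_date = dt.date(
            birth_year, int(rng.integers(1, 13)), int(rng.integers(1, 29))
        )
        sex = "M" if rng.random() < config.male_fraction else "F"
        person = Person(person_id=f"P{i:06d}", sex=sex, birth_date=birth_date)
        persons.append(person)

        chain = _simulate_latent_chain(config, rng, birth_year)
        for state in chain:
            latent_rows.append(
                {
                    "person_id": person.person_id,
                    "age": state.age,
                    "year": state.year,
                    "gingivitis": state.gingivitis,
                    "periodontitis": state.periodontitis,
                    "caries": state.caries,
                    "caries_temp": state.caries_temp,
                    "caries_perm": state.caries_perm,
                }
            )
            if state.age not in visit_ages:
                continue
            offset = int(rng.integers(30, 181))
            visit_date = birth_date + dt.timedelta(
                days=round(state.age * 365.25) + offset
            )
            if visit_date.year < 1972:
                continue
            regime = "annual" if visit_date.year < REGIME_CHANGE_YEAR else "needs_based"
            sched = config.visit_schedule[regime]
            p_visit = sched.get(state.age, sched["default"])
            if rng.random() >= p_visit:
                continue
            era = era_of(visit_date)
            emit_state = state
            if (
                config.reporting_shock is not None
                and visit_date.year in shock_windows
            ):
                extra = config.reporting_shock - 1.0
                flips = {}
                for d in ("gingivitis", "periodontitis"):
                    if not getattr(state, d):
                        p_false = float(
                            np.clip(
                                extra
                                * config.prevalence_curves[d](state.age, state.year),
                                0.0,
                                1.0,
                            )
                        )
                        if rng.random() < p_false:
                            flips[d] = True
                if flips:
                    emit_state = replace(state, **flips)
            gingiva, pockets, pocket_flag, surfaces = emit_era_coding(
                emit_state,
                era,
                rng,
                detection=config.detection,
                code5_rate=config.code5_rate,
            )
            municipality = (
                _NONEXISTENT_MUNICIPALITY
                if rng.random() < 0.01
                else int(rng.choice(_MUNICIPALITIES))
            )
            records.append(
                VisitRecord(
                    person_id=person.person_id,
                    visit_date=visit_date,
                    report_year=_report_year(visit_date),
                    municipality_code=municipality,
                    era=era,
                    gingiva_codes=gingiva,
                    pocket_codes=pockets,
                    pocket_flag=pocket_flag,
                    surface_codes=surfaces,
                )
            )

    records, persons, ledger = inject_faults(records, persons, config, rng)
    latent = pd.DataFrame(latent_rows)
    return SimulationResult(persons=persons, records=records, ledger=ledger, latent=latent)


def inject_faults(
    records: Sequence[VisitRecord],
    persons: Sequence[Person],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[VisitRecord], list[Person], FaultLedger]:
    """Plant duplicates and faulty rows into clean records.

    Death faults: a sampled person receives a death date set one day
    before their last visit, making exactly that visit fall after death.
    Age faults: sampled rows (never of a death-faulted person) are moved
    past the 19th birthday and their disease fields blanked.  Duplicates:
    exact copies of sampled rows appended at the end.  The ledger lists
    the affected row indices per class; the classes are disjoint.
    """
    if config.duplicate_rate + config.faulty_death_rate + config.faulty_age_rate > 1.0:
        raise ValueError("fault-injection rates sum to more than 1 per row")
    records = list(records)
    persons = list(persons)
    ledger = FaultLedger()
    n = len(records)
    if n == 0:
        return records, persons, ledger

    person_index = {p.person_id: j for j, p in enumerate(persons)}
    by_person: dict[str, list[int]] = {}
    for idx, r in enumerate(records):
        by_person.setdefault(r.person_id, []).append(idx)

    # death-before-visit faults, one row per sampled person
    m_death = int(rng.binomial(n, config.faulty_death_rate))
    candidates = [
        pid
        for pid, idxs in by_person.items()
        if persons[person_index[pid]].death_date is None
    ]
    death_persons: set[str] = set()
    if m_death and candidates:
        chosen = rng.choice(len(candidates), size=min(m_death, len(candidates)), replace=False)
        for c in np.sort(chosen):
            pid = candidates[int(c)]
            idxs = by_person[pid]
            last = max(idxs, key=lambda j: records[j].visit_date)
            death = records[last].visit_date - dt.timedelta(days=1)
            j = person_index[pid]
            persons[j] = Person(
                person_id=pid,
                sex=persons[j].sex,
                birth_date=persons[j].birth_date,
                death_date=death,
            )
            ledger.death_rows.append(last)
            death_persons.add(pid)

    # age-out-of-range faults: move sampled rows past the 19th birthday
    m_age = int(rng.binomial(n, config.faulty_age_rate))
    age_candidates = [
        idx for idx, r in enumerate(records) if r.person_id not in death_persons
    ]
    if m_age and age_candidates:
        existing_keys = {r.identity_key() for r in records}
        chosen = rng.choice(
            len(age_candidates), size=min(m_age, len(age_candidates)), replace=False
        )
        for c in np.sort(chosen):
            idx = age_candidates[int(c)]
            r = records[idx]
            birth = persons[person_index[r.person_id]].birth_date
            offset = int(rng.integers(30, 181))
            while True:
                new_date = birth + dt.timedelta(days=round(19 * 365.25) + offset)
                mutated = VisitRecord(
                    person_id=r.person_id,
                    visit_date=new_date,
                    report_year=_report_year(new_date),
                    municipality_code=r.municipality_code,
                    era=era_of(new_date),
                )
                if mutated.identity_key() not in existing_keys:
                    break
                offset += 1
            existing_keys.add(mutated.identity_key())
            records[idx] = mutated
            ledger.age_rows.append(idx)

    # exact duplicates appended at the end
    m_dup = int(rng.binomial(len(records), config.duplicate_rate))
    if m_dup:
        chosen = np.sort(rng.choice(len(records), size=m_dup, replace=False))
        base = len(records)
        for k, c in enumerate(chosen):
            records.append(records[int(c)].copy())
            ledger.duplicate_rows.append(base + k)
    return records, persons, ledger
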