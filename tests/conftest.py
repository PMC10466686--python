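import datetime as dt

import numpy as np
import pytest

from scorkit.eras import CriteriaEra
from scorkit.records import (
    GINGIVA_ALPHABETS,
    POCKET_ALPHABETS,
    Person,
    VisitRecord,
)
from scorkit.simulate import SimulationConfig, simulate_cohort
from scorkit.teeth import PERMANENT_FDI, PRIMARY_FDI, SURFACES, index_teeth


@pytest.fixture(scope="session")
def clean_cohort():
    """Small cohort without injected faults, spanning all three eras."""
    cfg = SimulationConfig(
        n_individuals=80,
        birth_year_range=(1965, 2000),
        duplicate_rate=0.0,
        faulty_death_rate=0.0,
        faulty_age_rate=0.0,
        seed=424242,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def faulted_cohort():
    """Cohort with injected duplicates and both faulty classes."""
    cfg = SimulationConfig(
        n_individuals=120,
        birth_year_range=(1965, 2000),
        duplicate_rate=0.02,
        faulty_death_rate=0.01,
        faulty_age_rate=0.01,
        seed=20240917,
    )
    return cfg, simulate_cohort(cfg)


def make_person(pid="P0", sex="F", birth=dt.date(1980, 1, 1), death=None):
    return Person(person_id=pid, sex=sex, birth_date=birth, death_date=death)


def random_record(rng: np.random.Generator, era: CriteriaEra) -> VisitRecord:
    """A random small visit record drawn directly from the era's code
    alphabets — independent of the cohort generator's emission logic."""
    year0, year1 = era.year_range
    year = int(rng.integers(year0, (year1 or 2020) + 1))
    visit_date = dt.date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
    gingiva = {}
    if era is CriteriaEra.ERA1:
        dentition = "temporary" if rng.random() < 0.3 else "permanent"
        for tooth in index_teeth(era, dentition):
            if rng.random() < 0.9:
                gingiva[tooth] = str(rng.choice(sorted(GINGIVA_ALPHABETS[era])))
        pockets = {}
        pocket_flag = "X" if rng.random() < 0.2 else None
    else:
        for tooth in index_teeth(era, "permanent"):
            if rng.random() < 0.5:
                gingiva[tooth] = str(rng.choice(sorted(GINGIVA_ALPHABETS[era])))
        pockets = {}
        for tooth in index_teeth(era, "permanent"):
            if rng.random() < 0.5:
                pockets[tooth] = str(rng.choice(sorted(POCKET_ALPHABETS[era])))
        pocket_flag = None
    surfaces = {}
    n_surf = int(rng.integers(0, 9))
    teeth = list(PRIMARY_FDI) + list(PERMANENT_FDI)
    for _ in range(n_surf):
        tooth = int(rng.choice(teeth))
        surface = str(rng.choice(SURFACES))
        surfaces[(tooth, surface)] = int(rng.choice([0, 1, 2, 4, 5, 6]))
    return VisitRecord(
        person_id=f"R{int(rng.integers(0, 1000)):04d}",
        visit_date=visit_date,
        era=era,
        gingiva_codes=gingiva,
        pocket_codes=pockets,
        pocket_flag=pocket_flag,
        surface_codes=surfaces,
    )
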