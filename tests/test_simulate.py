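import datetime as dt

import numpy as np
import pytest

from scorkit.cleaning import exact_age_years, rounded_age
from scorkit.eras import CriteriaEra
from scorkit.harmonize import aggregate_visit
from scorkit.simulate import (
    LatentState,
    SimulationConfig,
    emit_era_coding,
    inject_faults,
    simulate_cohort,
)


def full_schedule():
    return {"annual": {"default": 1.0}, "needs_based": {"default": 1.0}}


def test_single_person_annual_schedule_spans_all_eras():
    # born 1982: ages 0–5 fall before 1988, age 18 falls in 2000, so a
    # full annual schedule must cross all three criteria eras
    cfg = SimulationConfig(
        n_individuals=1,
        birth_year_range=(1982, 1982),
        visit_schedule=full_schedule(),
        duplicate_rate=0.0,
        faulty_death_rate=0.0,
        faulty_age_rate=0.0,
        seed=1,
    )
    result = simulate_cohort(cfg)
    assert len(result.records) == 19
    eras = {r.era for r in result.records}
    assert eras == {CriteriaEra.ERA1, CriteriaEra.ERA2, CriteriaEra.ERA3}
    assert result.ledger.is_empty()
    assert len(result.latent) == 19


def test_zero_fault_rates_give_empty_ledger(clean_cohort):
    _, result = clean_cohort
    assert result.ledger.is_empty()


def test_same_seed_reproduces_byte_identical_output(tmp_path):
    cfg = SimulationConfig(n_individuals=20, birth_year_range=(1970, 1995), seed=5)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    assert a.persons == b.persons
    assert [r.identity_key() for r in a.records] == [
        r.identity_key() for r in b.records
    ]
    assert a.ledger.as_dict() == b.ledger.as_dict()
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
    c = simulate_cohort(SimulationConfig(n_individuals=20, birth_year_range=(1970, 1995), seed=6))
    assert [r.identity_key() for r in c.records] != [
        r.identity_key() for r in a.records
    ]


def test_visit_dates_round_to_the_planted_age(clean_cohort):
    _, result = clean_cohort
    persons = {p.person_id: p for p in result.persons}
    planted_ages = {
        (row.person_id, row.age) for row in result.latent.itertuples()
    }
    for r in result.records:
        birth = persons[r.person_id].birth_date
        assert (r.person_id, rounded_age(birth, r.visit_date)) in planted_ages
        assert 0 < exact_age_years(birth, r.visit_date) < 19


def test_report_year_attribution_rules(clean_cohort):
    _, result = clean_cohort
    for r in result.records:
        year = r.visit_date.year
        if year >= 2000:
            assert r.report_year is None
        elif year <= 1987 and r.visit_date.month >= 8:
            assert r.report_year == year + 1
        else:
            assert r.report_year == year


class TestEmission:
    def healthy(self, age=10, year=1995):
        return LatentState(age, year, False, False, False, 0, 0)

    def test_all_healthy_era2_emits_all_blank(self):
        rng = np.random.default_rng(0)
        g, p, flag, s = emit_era_coding(self.healthy(), CriteriaEra.ERA2, rng)
        assert g == {} and p == {} and flag is None and s == {}

    @pytest.mark.parametrize("era", list(CriteriaEra))
    def test_positive_emission_crosses_thresholds(self, era):
        rng = np.random.default_rng(1)
        state = LatentState(15, 1985 if era is CriteriaEra.ERA1 else 2005,
                            True, True, True, 0, 7)
        for _ in range(50):
            g, p, flag, s = emit_era_coding(state, era, rng, detection=1.0)
            from scorkit.harmonize import gingivitis_flag, gingivitis_score
            from scorkit.harmonize import periodontitis_flag, pocket_count
            score = gingivitis_score(era, g)
            assert gingivitis_flag(era, score)
            assert periodontitis_flag(era, pocket_count(era, p, flag))
            dmf = sum(1 for c in s.values() if c in (1, 2, 4, 6))
            assert dmf == 7

    def test_latent_caries_surfaces_recovered_by_international_dmf(self):
        rng = np.random.default_rng(2)
        state = LatentState(10, 1995, False, False, True, 3, 4)
        for _ in range(20):
            _, _, _, s = emit_era_coding(state, CriteriaEra.ERA2, rng)
            record = {"surface_codes": s}
            from scorkit.harmonize import dmf_surfaces
            assert dmf_surfaces(s, "temporary", CriteriaEra.ERA2) == 3
            assert dmf_surfaces(s, "permanent", CriteriaEra.ERA2) == 4


def test_harmonized_flags_reproduce_latent_truth_at_full_detection(clean_cohort):
    """Generator → harmonization round trip: per-visit flag equivalence."""
    _, result = clean_cohort
    persons = {p.person_id: p for p in result.persons}
    latent = result.latent.set_index(["person_id", "age"])
    assert len(result.records) > 300
    for r in result.records:
        age = rounded_age(persons[r.person_id].birth_date, r.visit_date)
        truth = latent.loc[(r.person_id, age)]
        agg = aggregate_visit(r)
        assert agg.gingivitis_flag == bool(truth.gingivitis)
        assert agg.periodontitis_flag == bool(truth.periodontitis)
        assert agg.dmf_s == int(truth.caries_temp)
        assert agg.DMF_S == int(truth.caries_perm)


class TestInjectFaults:
    def test_duplicate_count_and_file_length(self):
        cfg = SimulationConfig(
            n_individuals=30,
            birth_year_range=(1975, 1995),
            duplicate_rate=0.1,
            faulty_death_rate=0.0,
            faulty_age_rate=0.0,
            seed=9,
        )
        clean = simulate_cohort(
            SimulationConfig(
                n_individuals=30, birth_year_range=(1975, 1995),
                duplicate_rate=0.0, faulty_death_rate=0.0, faulty_age_rate=0.0, seed=9
            )
        )
        rng = np.random.default_rng(77)
        records, persons, ledger = inject_faults(
            clean.records, clean.persons, cfg, rng
        )
        n_dup = len(ledger.duplicate_rows)
        assert n_dup > 0
        assert len(records) == len(clean.records) + n_dup
        for idx in ledger.duplicate_rows:
            assert any(
                records[idx].identity_key() == records[j].identity_key()
                for j in range(len(clean.records))
            )

    def test_age_faults_move_visits_outside_eligibility(self, faulted_cohort):
        _, result = faulted_cohort
        persons = {p.person_id: p for p in result.persons}
        assert result.ledger.age_rows
        for idx in result.ledger.age_rows:
            r = result.records[idx]
            assert exact_age_years(persons[r.person_id].birth_date, r.visit_date) >= 19

    def test_death_faults_place_visit_after_death(self, faulted_cohort):
        _, result = faulted_cohort
        persons = {p.person_id: p for p in result.persons}
        assert result.ledger.death_rows
        for idx in result.ledger.death_rows:
            r = result.records[idx]
            death = persons[r.person_id].death_date
            assert death is not None and death < r.visit_date

    def test_ledger_classes_disjoint_and_rows_exist(self, faulted_cohort):
        _, result = faulted_cohort
        ledger = result.ledger
        classes = [set(ledger.duplicate_rows), set(ledger.death_rows), set(ledger.age_rows)]
        assert sum(len(c) for c in classes) == len(set().union(*classes))
        for c in classes:
            assert all(0 <= i < len(result.records) for i in c)

    def test_overfull_rates_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(
                duplicate_rate=0.5, faulty_death_rate=0.4, faulty_age_rate=0.2
            ).validate()


def test_degenerate_config_rejected():
    with pytest.raises(ValueError, match="empty birth year range"):
        SimulationConfig(birth_year_range=(2000, 1990)).validate()
    with pytest.raises(ValueError, match="n_individuals"):
        SimulationConfig(n_individuals=0).validate()
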