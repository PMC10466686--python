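import datetime as dt

import numpy as np
import pandas as pd
import pytest

from scorkit.cleaning import clean_pipeline
from scorkit.harmonize import aggregates_frame
from scorkit.records import VisitRecord
from scorkit.summaries import (
    AGE_PERIODS,
    age_period,
    compare_population,
    entry_statistics,
    mean_entries_by_disease_state,
    period_coverage,
    prevalence_by,
    visits_by_year,
)

from conftest import make_person


def visits_at(pid, birth, ages):
    return [
        VisitRecord(
            person_id=pid,
            visit_date=birth + dt.timedelta(days=round(a * 365.25) + 100),
        )
        for a in ages
    ]


@pytest.fixture(scope="module")
def harmonized(faulted_cohort):
    _, result = faulted_cohort
    cleaned, _, _ = clean_pipeline(result.records, result.persons)
    agg = aggregates_frame(cleaned, result.persons)
    return result, cleaned, agg


class TestEntryStatistics:
    def test_hand_computed_mean_sd_min_max(self):
        birth = dt.date(1980, 1, 1)
        persons = [make_person(f"P{i}", "F", birth) for i in range(3)]
        records = (
            visits_at("P0", birth, [1, 2])
            + visits_at("P1", birth, [1, 2, 3, 4])
            + visits_at("P2", birth, [1, 2, 3, 4, 5, 6])
        )
        out = entry_statistics(records, persons)
        row = out.loc["all"]
        assert row["n_individuals"] == 3
        assert row["mean"] == 4 and row["sd"] == 2
        assert row["min"] == 2 and row["max"] == 6

    def test_single_individual_sd_undefined(self):
        birth = dt.date(1980, 1, 1)
        out = entry_statistics(
            visits_at("P0", birth, [3, 4, 5]), [make_person("P0", "M", birth)]
        )
        assert out.loc["all", "mean"] == 3
        assert np.isnan(out.loc["all", "sd"])

    def test_empty_group_absent(self):
        birth = dt.date(1980, 1, 1)
        persons = [make_person("P0", "F", birth), make_person("P1", "M", dt.date(1990, 1, 1))]
        out = entry_statistics(visits_at("P0", birth, [3]), persons, group_by="sex")
        assert list(out.index) == ["F"]


class TestPeriodCoverage:
    def test_periods_partition_ages_0_18(self):
        assert [age_period(a) for a in range(19)] == (
            [1] * 7 + [2] * 5 + [3] * 3 + [4] * 4
        )
        assert AGE_PERIODS == ((0, 6), (7, 11), (12, 14), (15, 18))

    @pytest.mark.parametrize(
        "ages, n_periods",
        [((3, 8, 13, 16), 4), ((3, 4, 5), 1), ((6, 7), 2)],
    )
    def test_distinct_period_counts(self, ages, n_periods):
        birth = dt.date(1980, 1, 1)
        out = period_coverage(
            visits_at("P0", birth, ages), [make_person("P0", "F", birth)]
        )
        assert out.loc[n_periods, "count_total"] == 1
        assert out["count_total"].sum() == 1

    def test_proportions_sum_to_one_and_counts_to_individuals(self, harmonized):
        result, cleaned, _ = harmonized
        out = period_coverage(cleaned, result.persons)
        n_people = len({r.person_id for r in cleaned})
        assert out["count_total"].sum() == n_people
        for col in ("prop_F", "prop_M", "prop_total"):
            assert out[col].sum() == pytest.approx(1.0)
        assert (out["count_F"] + out["count_M"]).equals(out["count_total"])


class TestPrevalence:
    def test_simple_arithmetic(self):
        agg = pd.DataFrame(
            {
                "person_id": [f"P{i}" for i in range(10)],
                "visit_year": [1995] * 10,
                "sex": ["F"] * 10,
                "age": [15] * 10,
                "gingivitis_flag": [True, True] + [False] * 8,
                "periodontitis_flag": [False] * 10,
                "dmf_total": [0] * 10,
            }
        )
        out = prevalence_by(agg, "gingivitis", "year_age")
        row = out.iloc[0]
        assert row["n_at_risk"] == 10 and row["n_positive"] == 2
        assert row["prevalence_per_1000"] == 200.0

    def test_zero_positive_gives_zero_rate(self):
        agg = pd.DataFrame(
            {
                "person_id": ["P0", "P1"],
                "visit_year": [2001, 2001],
                "sex": ["F", "M"],
                "age": [9, 9],
                "gingivitis_flag": [False, False],
                "periodontitis_flag": [False, False],
                "dmf_total": [0, 0],
            }
        )
        out = prevalence_by(agg, "caries", "year_sex")
        assert (out["prevalence_per_1000"] == 0).all()

    def test_bounds_and_consistency_on_cohort(self, harmonized):
        _, _, agg = harmonized
        for disease in ("gingivitis", "periodontitis", "caries"):
            for strata in ("year_sex", "year_age"):
                out = prevalence_by(agg, disease, strata)
                assert (out["n_positive"] <= out["n_at_risk"]).all()
                assert out["prevalence_per_1000"].between(0, 1000).all()
                recomputed = 1000.0 * out["n_positive"] / out["n_at_risk"]
                assert np.allclose(out["prevalence_per_1000"], recomputed)


class TestVisitsByYear:
    def test_attribution_rules(self):
        records = [
            VisitRecord(
                person_id="P0", visit_date=dt.date(1987, 10, 1), report_year=1988
            ),
            VisitRecord(person_id="P0", visit_date=dt.date(2005, 3, 3)),
        ]
        by_visit = visits_by_year(records, "visit_year")
        by_report = visits_by_year(records, "report_year")
        assert by_visit.loc[1987] == 1 and by_visit.loc[2005] == 1
        assert by_report.loc[1988] == 1 and by_report.loc[2005] == 1
        assert 1987 not in by_report.index

    def test_totals_conserved_across_axes(self, harmonized):
        result, cleaned, _ = harmonized
        for rows in (result.records, cleaned):
            assert (
                visits_by_year(rows, "visit_year").sum()
                == visits_by_year(rows, "report_year").sum()
                == len(rows)
            )


class TestComparePopulation:
    def denom(self, years, n):
        return pd.DataFrame({"birth_year": list(years), "n": n})

    def test_surplus_in_absolute_and_percent(self):
        persons = [
            make_person(f"P{i}", "F", dt.date(1980, 6, 1)) for i in range(104)
        ]
        table, totals = compare_population(persons, self.denom([1980], [100]))
        assert table.loc[0, "difference"] == 4
        assert table.loc[0, "pct_difference"] == pytest.approx(4.0)
        assert totals["difference"] == 4

    def test_equal_counts_give_zero(self):
        persons = [make_person("P0", "F", dt.date(1980, 6, 1))]
        table, totals = compare_population(persons, self.denom([1980], [1]))
        assert totals["difference"] == 0 and totals["pct_difference"] == 0.0

    def test_missing_denominator_year_names_the_year(self):
        persons = [make_person("P0", "F", dt.date(1985, 6, 1))]
        with pytest.raises(ValueError, match="1985"):
            compare_population(persons, self.denom([1980], [1]))

    def test_zero_denominator_marks_percentage_undefined(self):
        persons = [make_person("P0", "F", dt.date(1980, 6, 1))]
        table, _ = compare_population(persons, self.denom([1980], [0]))
        assert np.isnan(table.loc[0, "pct_difference"])


class TestMeanEntriesByDiseaseState:
    def test_caries_group_uses_max_dmf_over_visits(self):
        birth = dt.date(1990, 1, 1)
        records = visits_at("P0", birth, [5, 9, 15])
        agg = pd.DataFrame(
            {
                "person_id": ["P0"] * 3,
                "visit_year": [1995, 1999, 2005],
                "gingivitis_flag": [False] * 3,
                "periodontitis_flag": [False] * 3,
                "dmf_total": [0, 3, 11],
            }
        )
        out = mean_entries_by_disease_state(records, agg)
        caries = out[out["disease"] == "caries"].set_index("group")
        assert list(caries.index) == [">=10"]
        assert caries.loc[">=10", "mean_entries"] == 3

    def test_never_flagged_individual_in_never_groups(self):
        birth = dt.date(1990, 1, 1)
        records = visits_at("P0", birth, [5])
        agg = pd.DataFrame(
            {
                "person_id": ["P0"],
                "visit_year": [1995],
                "gingivitis_flag": [False],
                "periodontitis_flag": [False],
                "dmf_total": [2],
            }
        )
        out = mean_entries_by_disease_state(records, agg).set_index(
            ["disease", "group"]
        )
        assert ("gingivitis", "never") in out.index
        assert ("periodontitis", "never") in out.index
        assert ("caries", "0-4") in out.index

    def test_by_year_variant_groups_by_that_years_state(self, harmonized):
        _, cleaned, agg = harmonized
        out = mean_entries_by_disease_state(cleaned, agg, by_year=True)
        assert set(out["disease"]) <= {"gingivitis", "periodontitis", "caries"}
        assert (out["n_individuals"] > 0).all()
        assert (out["mean_entries"] > 0).all()
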