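"""Descriptive cohort outputs from cleaned, harmonized records.

All operations take cleaned visit records (and the per-visit aggregate
table from :mod:`scorkit.harmonize`) and return tidy pandas DataFrames:
per-person entry statistics, coverage of the four age periods of care
eligibility (0–6, 7–11, 12–14, 15–18 years), prevalence per 1000 by
calendar year and sex or age, visit counts by year of visit vs year of
report, comparison against external population denominators, and mean
entry counts by disease state.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .cleaning import rounded_age
from .records import Person, VisitRecord, persons_by_id

__all__ = [
    "AGE_PERIODS",
    "compare_population",
    "entry_statistics",
    "mean_entries_by_disease_state",
    "period_coverage",
    "prevalence_by",
    "records_frame",
    "visits_by_year",
]

log = logging.getLogger(__name__)

#: The four age periods of eligibility for care, a partition of ages 0–18.
AGE_PERIODS: tuple[tuple[int, int], ...] = ((0, 6), (7, 11), (12, 14), (15, 18))


def age_period(age: int) -> int:
    """1-based index of the age period containing an integer age."""
    for k, (lo, hi) in enumerate(AGE_PERIODS, start=1):
        if lo <= age <= hi:
            return k
    raise ValueError(f"age {age} outside 0–18")


def records_frame(
    records: Iterable[VisitRecord],
    persons: Iterable[Person] | Mapping[str, Person],
) -> pd.DataFrame:
    """Flat visit table: ids, dates, era, sex, birth year, rounded age."""
    lookup = persons_by_id(persons)
    rows = []
    for r in records:
        p = lookup[r.person_id]
        rows.append(
            {
                "person_id": r.person_id,
                "visit_date": r.visit_date,
                "visit_year": r.visit_date.year,
                "report_year": r.report_year,
                "era": r.era.value,
                "sex": p.sex,
                "birth_year": p.birth_date.year,
                "age": rounded_age(p.birth_date, r.visit_date),
            }
        )
    return pd.DataFrame(rows)


def entry_statistics(
    records: Iterable[VisitRecord],
    persons: Iterable[Person] | Mapping[str, Person],
    group_by: Literal["sex", "birth_year"] | None = None,
) -> pd.DataFrame:
    """Mean, sample SD (n−1), minimum and maximum entries per individual.

    With ``group_by`` the statistics are computed within each sex or birth
    year; the SD of a single-individual group is reported as NaN (the
    undefined marker).  Individuals without records do not contribute.
    """
    frame = records_frame(records, persons)
    if frame.empty:
        return pd.DataFrame(
            columns=["group", "n_individuals", "mean", "sd", "min", "max"]
        ).set_index("group")
    per_person = (
        frame.groupby(["person_id"])
        .agg(n_entries=("visit_date", "size"), sex=("sex", "first"),
             birth_year=("birth_year", "first"))
        .reset_index()
    )
    if group_by is None:
        per_person["group"] = "all"
    else:
        per_person["group"] = per_person[group_by]
    out = per_person.groupby("group")["n_entries"].agg(
        n_individuals="size", mean="mean", sd=lambda s: s.std(ddof=1),
        min="min", max="max"
    )
    return out[["n_individuals", "mean", "sd", "min", "max"]]


def period_coverage(
    records: Iterable[VisitRecord],
    persons: Iterable[Person] | Mapping[str, Person],
) -> pd.DataFrame:
    """Distribution of individuals by number of age periods covered.

    Rows: 1–4 distinct periods with at least one entry; columns: counts
    and proportions per sex and in total.  Proportions in each column sum
    to 1 and counts sum to the number of individuals with records.
    """
    frame = records_frame(records, persons)
    frame["period"] = frame["age"].map(age_period)
    per_person = frame.groupby("person_id").agg(
        n_periods=("period", "nunique"), sex=("sex", "first")
    )
    out = pd.DataFrame(index=pd.Index([1, 2, 3, 4], name="n_periods"))
    for label, sub in (
        ("F", per_person[per_person["sex"] == "F"]),
        ("M", per_person[per_person["sex"] == "M"]),
        ("total", per_person),
    ):
        counts = sub["n_periods"].value_counts().reindex([1, 2, 3, 4], fill_value=0)
        out[f"count_{label}"] = counts
        out[f"prop_{label}"] = counts / counts.sum() if counts.sum() else np.nan
    return out


def prevalence_by(
    aggregates: pd.DataFrame,
    disease: Literal["gingivitis", "periodontitis", "caries"],
    strata: Literal["year_sex", "year_age"] = "year_sex",
    ages: tuple[int, ...] = (5, 9, 15),
    caries_threshold: int = 1,
) -> pd.DataFrame:
    """Prevalence per 1000 individuals by calendar year and sex or age.

    ``aggregates`` is the table from
    :func:`scorkit.harmonize.aggregates_frame` built with a person table
    (so sex and age columns are present).  An individual counts as at risk
    in a stratum when they have at least one visit in it, and as positive
    when any of those visits is positive: the harmonized flag for
    gingivitis/periodontitis, or a total DMF-S of at least
    ``caries_threshold`` (caries experience) for caries.  Ages other than
    the requested ones (default 5, 9 and 15 — temporary, mixed and
    permanent dentition) are ignored under ``year_age``.
    """
    if disease == "caries":
        positive = aggregates["dmf_total"] >= caries_threshold
    else:
        positive = aggregates[f"{disease}_flag"].astype(bool)
    work = aggregates.assign(positive=positive)
    if strata == "year_sex":
        keys = ["visit_year", "sex"]
    elif strata == "year_age":
        keys = ["visit_year", "age"]
        work = work[work["age"].isin(ages)]
        if work.empty:
            log.info("no visits at the requested ages; empty prevalence table")
    else:
        raise ValueError(f"unknown strata {strata!r}")
    per_individual = work.groupby(keys + ["person_id"])["positive"].any().reset_index()
    out = per_individual.groupby(keys)["positive"].agg(
        n_at_risk="size", n_positive="sum"
    )
    out["prevalence_per_1000"] = 1000.0 * out["n_positive"] / out["n_at_risk"]
    return out.reset_index()


def visits_by_year(
    records: Iterable[VisitRecord],
    axis: Literal["visit_year", "report_year"] = "visit_year",
) -> pd.Series:
    """Visit counts per calendar year on either attribution axis.

    The report axis uses the stored year of report where present (it
    disappears from the registry with the 2000 criteria change) and falls
    back to the year of visit from 2000 on.  Both axes distribute the same
    records, so their totals are equal.
    """
    if axis == "visit_year":
        years = [r.visit_date.year for r in records]
    elif axis == "report_year":
        years = [
            r.report_year if r.report_year is not None else r.visit_date.year
            for r in records
        ]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    counts = pd.Series(years, dtype=int).value_counts().sort_index()
    counts.index.name = axis
    counts.name = "n_visits"
    return counts


def compare_population(
    persons: Iterable[Person] | Mapping[str, Person],
    denominators: pd.DataFrame | pd.Series,
    year_range: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Registry headcount vs external birth-cohort denominators.

    ``denominators`` maps birth year → expected population (births plus
    child naturalizations); a DataFrame needs columns ``birth_year`` and
    ``n``.  Returns a per-year table of absolute (registry − denominator)
    and percentage differences, plus totals over ``year_range`` (default:
    all registry birth years).  A zero denominator yields a NaN
    percentage; a denominator missing for a requested year is an error
    naming the year.
    """
    if isinstance(denominators, pd.DataFrame):
        denom = denominators.set_index("birth_year")["n"]
    else:
        denom = denominators
    lookup = persons_by_id(persons)
    registry = pd.Series(
        [p.birth_date.year for p in lookup.values()], dtype=int
    ).value_counts().sort_index()
    years = (
        range(year_range[0], year_range[1] + 1)
        if year_range is not None
        else registry.index
    )
    rows = []
    for year in years:
        if year not in denom.index:
            raise ValueError(f"no population denominator for birth year {year}")
        n_reg = int(registry.get(year, 0))
        n_den = int(denom.loc[year])
        diff = n_reg - n_den
        rows.append(
            {
                "birth_year": year,
                "n_registry": n_reg,
                "n_denominator": n_den,
                "difference": diff,
                "pct_difference": 100.0 * diff / n_den if n_den else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    total_reg = int(table["n_registry"].sum())
    total_den = int(table["n_denominator"].sum())
    totals = {
        "n_registry": total_reg,
        "n_denominator": total_den,
        "difference": total_reg - total_den,
        "pct_difference": (
            100.0 * (total_reg - total_den) / total_den if total_den else np.nan
        ),
    }
    return table, totals


def _caries_group(max_dmf: int) -> str:
    if max_dmf >= 10:
        return ">=10"
    if max_dmf >= 5:
        return "5-9"
    return "0-4"


def mean_entries_by_disease_state(
    records: Iterable[VisitRecord],
    aggregates: pd.DataFrame,
    by_year: bool = False,
) -> pd.DataFrame:
    """Mean number of entries per individual by disease state.

    Gingivitis and periodontitis group individuals as ever vs never
    flagged across their visits; caries groups by the individual's highest
    total DMF-S at any visit, in the 0–4 / 5–9 / ≥ 10 surface bands.  With
    ``by_year`` the grouping is instead per calendar year by that year's
    state, and the mean is over each individual's total entry count among
    individuals seen that year.
    """
    entries = (
        pd.Series([r.person_id for r in records], name="person_id")
        .value_counts()
        .rename("n_entries")
    )
    agg = aggregates
    rows = []
    groupings: dict[str, pd.Series] = {}
    if not by_year:
        per_person = agg.groupby("person_id").agg(
            ging=("gingivitis_flag", "any"),
            perio=("periodontitis_flag", "any"),
            max_dmf=("dmf_total", "max"),
        )
        groupings["gingivitis"] = per_person["ging"].map({True: "ever", False: "never"})
        groupings["periodontitis"] = per_person["perio"].map(
            {True: "ever", False: "never"}
        )
        groupings["caries"] = per_person["max_dmf"].map(_caries_group)
        for disease, groups in groupings.items():
            frame = pd.DataFrame({"group": groups}).join(entries)
            for group, sub in frame.groupby("group"):
                rows.append(
                    {
                        "disease": disease,
                        "group": group,
                        "n_individuals": len(sub),
                        "mean_entries": float(sub["n_entries"].mean()),
                    }
                )
        return pd.DataFrame(rows)

    per_py = agg.groupby(["visit_year", "person_id"]).agg(
        ging=("gingivitis_flag", "any"),
        perio=("periodontitis_flag", "any"),
        max_dmf=("dmf_total", "max"),
    )
    per_py = per_py.join(entries, on="person_id")
    per_py["gingivitis"] = per_py["ging"].map({True: "yes", False: "no"})
    per_py["periodontitis"] = per_py["perio"].map({True: "yes", False: "no"})
    per_py["caries"] = per_py["max_dmf"].map(_caries_group)
    for disease in ("gingivitis", "periodontitis", "caries"):
        grouped = per_py.reset_index().groupby(["visit_year", disease])["n_entries"]
        for (year, group), sub in grouped:
            rows.append(
                {
                    "disease": disease,
                    "year": int(year),
                    "group": group,
                    "n_individuals": len(sub),
                    "mean_entries": float(sub.mean()),
                }
            )
    return pd.DataFrame(rows)
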