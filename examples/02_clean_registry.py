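"""Run the registry cleaning procedure and audit it against the ledger.

Cleaning removes exact duplicates, visits after the person's death,
visits at ages outside the 0 < age < 19 eligibility window, and finally
restricts each person to one entry per integer year of age (earliest
visit wins).  On synthetic data the per-rule counts must equal the fault
ledger exactly — nothing more, nothing less.
"""

from scorkit import SimulationConfig, clean_pipeline, simulate_cohort

config = SimulationConfig(
    n_individuals=200,
    birth_year_range=(1965, 2000),
    duplicate_rate=0.01,
    faulty_death_rate=0.005,
    faulty_age_rate=0.005,
    seed=42,
)
result = simulate_cohort(config)
cleaned, report, unresolved = clean_pipeline(result.records, result.persons)

print("cleaning report (rows):")
for key, value in report.as_dict().items():
    print(f"  {key:28s} {value}")
print(
    "conservation holds:",
    report.conserves_rows(),
    "| idempotent:",
    clean_pipeline(cleaned, result.persons)[1].n_input
    == clean_pipeline(cleaned, result.persons)[1].n_output,
)
print(
    f"ledger check: duplicates {report.n_duplicates_removed} == "
    f"{len(result.ledger.duplicate_rows)}, death "
    f"{report.n_death_removed} == {len(result.ledger.death_rows)}, age "
    f"{report.n_age_removed} == {len(result.ledger.age_rows)}"
)
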