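"""Generate a small synthetic registry and look at what it contains.

The generator plants per-(person, age) disease truth, schedules visits by
the reporting regime of each calendar year, codes every visit under the
criteria era of its date, and injects duplicates and faulty rows that a
fault ledger records as ground truth.
"""

from scorkit import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_individuals=200,
    birth_year_range=(1965, 2000),
    duplicate_rate=0.01,
    faulty_death_rate=0.005,
    faulty_age_rate=0.005,
    seed=42,
)
result = simulate_cohort(config)

print(f"persons:            {len(result.persons)}")
print(f"visit records:      {len(result.records)}")
for era in ("era1", "era2", "era3"):
    n = sum(1 for r in result.records if r.era.value == era)
    print(f"  coded under {era}: {n}")
print(f"injected duplicates:        {len(result.ledger.duplicate_rows)}")
print(f"injected death-before-visit: {len(result.ledger.death_rows)}")
print(f"injected out-of-range ages:  {len(result.ledger.age_rows)}")

truth_at_15 = result.latent.query("age == 15")
print(
    f"planted gingivitis prevalence at age 15: "
    f"{truth_at_15['gingivitis'].mean():.3f} "
    f"(the default curve plants 0.30)"
)

# result.write("sim_out")  # emits persons.csv, visits_era*.csv, ledger, truth
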