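# Methods

This note documents the scientific and numerical choices behind scorkit:
what the harmonization rules are, what the synthetic registry does and
does not emulate, and where the design was genuinely open.

## Criteria eras and tooth notation

All scoring logic is keyed on the three registration-criteria eras
(1972–1987, 1988–1999, 2000–present).  The registry's *datasets* split at
different years (1988 and 1995); because every aggregate rule is defined
per criteria era, dataset-of-origin is carried only as an opaque extra
column, never used by any computation.

Teeth are identified by two-digit FDI codes throughout; conversion to and
from the Danish Haderup notation used on the original forms is a
verified bijection on all 52 valid codes (32 permanent + 20 primary).
The 1972–1987 index teeth (four per dentition) admit nearest-neighbour
substitution when missing: same quadrant, smallest positional distance,
ties broken toward the lower position number.  The tie-break is a
package decision — the historical instruction names only "the nearest
neighboring tooth" — chosen to be deterministic and documented.  When the
quadrant holds no tooth, the registration is reported unscorable rather
than silently imputed.  No substitution is applied for the 1988+ twelve
permanent index teeth.

## Harmonized aggregates

Per visit, scorkit computes:

* gingivitis score: 1972–1987 the sum of the four 0–3 grades; 1988–1999
  the count of index teeth coded 2; 2000+ the count coded 1.  Flag at
  score ≥ 9 (pre-1988) or ≥ 6 of 12 (after).  The ≥ 9 cut-off is exactly
  the least total that forces a grade-3 tooth, which the test suite and
  acceptance script verify by enumerating all 4⁴ grade assignments.
* pocket count: 1972–1987 the record-level X/NA flag (an X on any index
  tooth is accepted as an equivalent input); 1988–1999 the count of teeth
  coded 5 — code 4 (pockets without attachment loss) never contributes
  and is exposed only as a diagnostic column; 2000+ the sum of the twelve
  0/1 indicators.  Flag on X (pre-1988) or count ≥ 6 (after).
* DMF-S: count of surfaces coded 1, 2, 4 or 6, split by dentition
  (FDI quadrants 5–8 = temporary, 1–4 = permanent); `dmf_total` is their
  sum.  The `scor_provided` variant additionally counts code 5 in the
  temporary dentition from 1988 on, reproducing the registry's own
  variable; the default `international` variant omits code 5 everywhere.
  Surface-code semantics are deliberately treated as opaque labels — only
  the counting rules above are modelled.

Three blank-handling decisions matter:

* Blanks score 0 and flag negative in every era, matching the aggregate
  definitions.  Because a fully blank gingiva form (1988+) or pocket form
  (pre-2000) is indistinguishable from an examination never made, each
  aggregate row carries `gingiva_unregistered` / `pockets_unregistered`
  indicators so analysts can stratify on the ambiguity instead of
  inheriting it silently.
* The per-tooth code X (missing registration tooth, 1988+) contributes 0
  to both the gingivitis level and the pocket sum.  The registration
  guidelines do not prescribe a treatment; counting a missing tooth as
  non-positive is the conservative choice and is applied uniformly.
* The 1988+ gingiva alphabets include X alongside the disease codes,
  since the registration scheme prints it; it never scores.

Code alphabets are closed per era: any symbol outside them is a parse or
contract error, never coerced.

## The synthetic registry

The generator exists because the real registry is access-restricted; it
emulates the registry's *structure* well enough that every downstream
stage has an exact oracle, and makes no claim to biological realism.

**Latent disease.**  Per person, each disease follows a yearly Bernoulli
chain over ages 0–18: with probability `persistence` (default 0.7) the
previous year's state is carried, otherwise the state is redrawn with a
probability adjusted so the marginal prevalence at every age equals the
configured prevalence curve exactly.  Persistence exists so longitudinal
summaries (ever/never grouping, per-person maxima) are non-degenerate;
0.7 is a round default in the plausible range for chronic-ish childhood
conditions.  Default curves (order-of-magnitude placeholders, since no
published numeric prevalences exist to calibrate against): gingivitis
ramps from
5 % to 30 % at age 15; periodontitis is rare before age 10 and reaches
~10 % by 18; caries risk rises with age and carries a linear secular
decline to half its 1972 level by 2021.  Carious-surface counts grow by a
small Poisson increment while the state persists and are split between
dentitions by an age-dependent fraction (all temporary before age 6, all
permanent after 12, linear in between) — a simplification standing in for
real eruption timing.

**Coding.**  A latently positive disease is coded above the harmonized
threshold with probability `detection` (default 1.0) and left blank
otherwise; health is coded blank under the 1988+ gingiva and pocket
schemes (reproducing the blank ambiguity) and with sub-threshold grades
under the mandatory 1972–1987 gingiva scheme.  At detection 1 the
harmonized flags and DMF counts reproduce the latent truth exactly,
visit by visit — the round-trip property the test suite enforces.  An
optional `reporting_shock` multiplier codes some latent-negative visits
positive for two calendar years after the 1988 and 2000 criteria changes,
modelling over-reporting around registration changes; it defaults to off
and is not part of any oracle test.

**Visits.**  One visit at most per age, dated 30–180 days after the
birthday — so the exact age always lies strictly inside the eligibility
window and rounds to the planted age.  Visit probability comes from the
calendar-year regime: annual reporting before 1993 (default 0.95 per
age), needs-based after (0.95 at the mandatory ages 5/7/12/15, 0.55
otherwise, reflecting that reported visits never actually collapsed onto
the mandatory ages).  Report years follow the school year through 1987
(August+ reports to the next year), the calendar year 1988–1999, and are
absent from 2000 on.  Visits predating 1972 are not emitted.

**Faults.**  Exact duplicates are appended copies of sampled rows.
Death faults plant a death date one day before a sampled person's last
visit, so exactly one ledgered row per sampled person violates the death
rule and no unledgered row does.  Age faults move sampled rows (never of
a death-faulted person) past the 19th birthday and blank their codes,
since a row relocated across an era boundary cannot keep codes from
another era's alphabet.  Default rates (2·10⁻⁴ duplicates, 2·10⁻⁴ death,
4·10⁻⁴ age) match the order of magnitude of removal fractions reported
for real registries of this kind; tests that need every class non-empty
at small n pass explicit larger rates as scenario configuration.  The
ledger's row classes are disjoint, and cleaning must reproduce them
count for count and row for row.

**What passing tests do not show.**  The generator emits at most one
visit per age (so the age-restriction stage removes nothing on clean
synthetic data and is exercised by constructed inputs), produces bimodal
1988+ scores (blank or ≥ threshold, no intermediate noise), and models no
municipality heterogeneity, eruption timing, examiner variation or
secular gingivitis trends.  Recovery of a planted prevalence therefore
validates the pipeline's arithmetic and bookkeeping, not any claim about
real registry data.

## Cleaning

Stages run in a fixed order — duplicates, then faulty records, then the
one-entry-per-age restriction — because the order affects the per-rule
counts.  "Duplicate" means equality on every field; near-duplicates
(same person and date, different codes) survive to the age restriction.
Faulty records are visits strictly after the death date (a visit on the
death date is kept) and visits at an exact age outside the open interval
0 < age < 19 years, with exact age = days / 365.25; a row violating both
rules counts under the death rule.  Rows whose person id does not
resolve go to a rejected-rows channel and appear in the report as
`n_unresolved_person`, so conservation (input = output + all removals)
holds on every input.

The integer age for the restriction rounds half down by default
(⌈age − ½⌉): deterministic, and an exact half-year never inflates the age
past a boundary.  Day-resolution dates can never actually land on a
half-year under the 365.25 divisor, so the choice only fixes the tie
rule; conventional epidemiological floor rounding is available via the
`rounding="floor"` switch.  Within a (person, age) cell the earliest
visit date wins; a same-date tie keeps the first row in stable input
order.  The pipeline is idempotent and its output has at most 19 rows
per person, one per integer age 0–18.

## Summaries

Entry statistics use the sample standard deviation (ddof = 1), reported
as NaN for single-individual groups.  Because pre- and post-restriction
entry counts genuinely differ, entry statistics can be computed on either
the cleaned or the raw record list; analysts wanting both maxima simply
run it twice.  Age-period coverage partitions ages 0–18 into 0–6 / 7–11 /
12–14 / 15–18 and counts distinct covered periods per individual.
Prevalence denominators are individuals with at least one visit in the
stratum (year × sex or year × age at 5/9/15), positive if any such visit
is positive; caries positivity is `dmf_total >= 1` — the conventional
caries-experience definition, exposed as a parameter because no single
cut-off is mandated.  The year-of-report axis uses the stored
report year where present and the visit year from 2000 on, so both axes
distribute the same records and their totals agree.  Mean entries by
disease state groups gingivitis and periodontitis as ever/never flagged
and caries by the per-individual maximum `dmf_total` in the 0–4 / 5–9 /
≥ 10 surface bands; a per-calendar-year variant groups by that year's
state instead (the grouping basis was an open choice; both are provided).
Population comparison against a user-supplied birth-year denominator
table reports absolute and percentage differences per year and in total;
no external data is downloaded.

## Numerical and interface choices

Dates are ISO 8601 in files; sex is F/M; blank codes are encoded by
absence.  Caries surfaces are packed into one column of
`<tooth><surface>:<code>` tokens rather than 260 sparse columns.
Nonexistent municipality codes are carried through and never referenced
by cleaning.  The YAML simulation config covers the scalar fields and the
visit schedule; prevalence curves are Python callables.  Problem sizes in
the test suite (cohorts of 80–500 persons for structural checks, 5,000
per era for prevalence recovery at a ±3-standard-error band) were chosen
so each check has the statistical resolution it claims — 5,000
individuals put three binomial standard errors at ±0.019 around the
planted 0.30.
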