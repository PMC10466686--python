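"""Compute era-comparable aggregate disease variables for single visits.

The three criteria eras scored gingivitis, pockets and caries
differently; the harmonized aggregates make them comparable: a 0–12
gingivitis score (flag at index >= 9 pre-1988, >= 6 of 12 teeth after), a
pocket count or X/NA flag for periodontitis, and DMF-S surface counts per
dentition.
"""

import datetime as dt

from scorkit import VisitRecord, aggregate_visit

# 1972–1987: four index teeth graded 0–3; one severe tooth pushes the
# index to 9, the harmonized gingivitis cut-off
era1 = VisitRecord(
    person_id="A",
    visit_date=dt.date(1980, 5, 1),
    gingiva_codes={12: "3", 16: "2", 42: "2", 46: "2"},
    surface_codes={(16, "O"): 1, (26, "M"): 2, (36, "B"): 4},
)
agg = aggregate_visit(era1)
print("1972–1987 visit:")
print(f"  gingivitis index {agg.gingivitis_score} -> flag {agg.gingivitis_flag}")
print(f"  pockets {agg.pocket_count} -> periodontitis {agg.periodontitis_flag}")
print(f"  DMF_S {agg.DMF_S} (permanent), dmf_s {agg.dmf_s} (temporary)")

# 2005 visit: seven of twelve index teeth bleeding, six pocket teeth,
# caries in both dentitions; code 5 surfaces count only under the
# registry's own temporary-dentition variant
era3 = VisitRecord(
    person_id="B",
    visit_date=dt.date(2005, 5, 1),
    gingiva_codes={t: "1" for t in (11, 12, 21, 22, 31, 32, 41)},
    pocket_codes={t: "1" for t in (16, 26, 36, 46, 11, 21)},
    surface_codes={(55, "O"): 1, (55, "M"): 5, (16, "O"): 2},
)
for variant in ("international", "scor_provided"):
    agg = aggregate_visit(era3, variant)
    print(f"2000+ visit, {variant} caries variant:")
    print(
        f"  gingivitis level {agg.gingivitis_score} -> flag {agg.gingivitis_flag}; "
        f"pockets {agg.pocket_count} -> periodontitis {agg.periodontitis_flag}; "
        f"dmf_s {agg.dmf_s}, DMF_S {agg.DMF_S}, total {agg.dmf_total}"
    )
print(
    "(the code-5 surface on tooth 55 is why the two variants disagree on "
    "the temporary dentition)"
)
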