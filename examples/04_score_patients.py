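"""Score individual patients against a fitted scoring table.

Builds a compact two-variable scorecard and applies it to a few patient
records; interval matching follows the "[A, B)" convention (a value on
a cut boundary belongs to the upper interval).
"""

import svscore as sv

cohort, _ = sv.generate_cohort(sv.default_ehr_spec(n=3000, seed=11))
cohort = sv.split_cohort(cohort, seed=2)
train = cohort.subset("train")

variables = ["ed_visits", "renal_disease"]
cuts = sv.derive_cuts(train, variables)
table = sv.assign_points(train, variables, cuts, cap=100)
print(table.to_markdown())

patients = [
    {"ed_visits": 0, "renal_disease": 0},
    {"ed_visits": 2, "renal_disease": 0},
    {"ed_visits": 6, "renal_disease": 1},
]
print()
for p in patients:
    print(f"  {p} -> score {sv.compute_score(table, p)}")

# The all-reference patient scores 0 and the all-worst patient scores
# the full cap; anything between is the sum of the matched rows.
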