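"""Generate the default synthetic cohort and inspect its structure.

The generator emulates a multi-site brain-morphometry study: 1157 subjects
(607 male, 550 female) spread over eight age bands from 14 to 89 years with
a bimodal age profile, and 34 segmented brain volumes per subject that drift
linearly with age (ventricles expand, parenchyma shrinks) plus a male-female
offset and Gaussian noise.
"""

from brainvqc import default_demographics, default_effects, generate_cohort

table = generate_cohort(default_demographics(), default_effects(), seed=7)

print(f"subjects: {len(table)}  "
      f"(M: {(table.sex == 'M').sum()}, F: {(table.sex == 'F').sum()})")
print(f"age range: {table.age.min():.1f}-{table.age.max():.1f} years, "
      f"mean {table.age.mean():.1f}")

# age effects in the expected directions: CSF spaces up, gray matter down
for feature in ("Left lateral ventricle", "Left hippocampus"):
    r = table[feature].corr(table["age"])
    print(f"corr(age, {feature}): {r:+.2f}")

# the male offset is visible as a mean volume difference
by_sex = table.groupby("sex")["Left thalamus proper"].mean()
print(f"Left thalamus proper mean (M - F): {by_sex['M'] - by_sex['F']:+.0f} mm^3")
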