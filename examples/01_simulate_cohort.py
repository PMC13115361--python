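"""Generate a synthetic CKD laboratory cohort and inspect its structure.

The generator emulates a single-centre renal-clinic dataset: one row per
patient, 39 routinely ordered features plus 21 rarely ordered ones
(around 80% missing), five ordinal classes (non-CKD, stages 3a/3b/4/5),
and stage-monotone shifts in renal and hematologic markers.
"""

from ckdtriage import default_cohort_spec, generate_cohort

spec = default_cohort_spec(n_patients=500, separation=1.0, seed=42)
cohort = generate_cohort(spec)

print(f"patients: {cohort.n_patients}, features: {len(cohort.feature_names)}")
print("class counts (0 = non-CKD, 1..4 = stages 3a, 3b, 4, 5):")
print(cohort.labels.value_counts().sort_index().to_string())

frac = cohort.missing_fraction().sort_values(ascending=False)
print("\nmost-missing features (the sparse block sits around 0.8):")
print(frac.head(5).round(3).to_string())

print("\nclass-conditional creatinine means (rise with stage):")
means = cohort.features["CREA"].groupby(cohort.labels).mean().round(2)
print(means.to_string())
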