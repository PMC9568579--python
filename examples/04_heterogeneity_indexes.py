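"""Per-patient CV profile and the two heterogeneity indexes.

On a synthetic feature table with a known angular spread, the average
tumoral heterogeneity (ATH, mean pairwise cosine dissimilarity) should sit
near its closed-form expectation, and the maximal tumoral divergence (MTD)
is the worst pair.
"""

from radhet import (
    cohort_indexes,
    cv_profile,
    expected_average_heterogeneity,
    generate_feature_table,
)

spread = 0.8
table = generate_feature_table(n_patients=3, n_lesions=25,
                               angular_spread=spread, n_features=8, rng=5)

cohort, per_patient = cohort_indexes(table, normalize=False)
print(per_patient[["n_lesions", "mtd", "ath"]]
      .to_string(float_format=lambda v: f"{v:.3f}"))
print(f"\ncohort MTD={cohort.mtd:.3f}  ATH={cohort.ath:.3f}  "
      f"(expected ATH ~ {expected_average_heterogeneity(spread):.3f})")

profile = cv_profile(table)
print("\nmean CV per patient (%):")
print(profile.pooled.to_string(float_format=lambda v: f"{v:.1f}"))

# MTD/ATH are bounded by 1.0; the cohort value is the unweighted mean over
# patients.  CVs are 100*|sd/mean| per feature across a patient's lesions.
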