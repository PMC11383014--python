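"""Recover planted tumor-vs-normal shifts with paired tests.

Simulates one cohort with 40 matched tumor/non-tumor patient pairs and 30
proteins up-shifted by one log2 unit in tumor samples, then runs the
differential-expression pipeline (paired t-tests, Benjamini-Hochberg,
adjusted p < 0.01 and |log2FC| > 0.5) directly on the observed values
(missing pairs dropped).
"""

import lupine as lp

spec = lp.SimSpec(n_cohorts=1, proteins_per_cohort=300, samples_per_cohort=80,
                  paired_patients_per_cohort=40, noise_sd=0.3,
                  n_de_proteins=30, de_log2_shift=1.0,
                  target_missing_fraction=0.25, seed=77)
observed, truth = lp.simulate_cohorts(spec)

table = lp.run_de(observed, observed, alpha=0.01, lfc_cut=0.5)
called = set(table.index[table["direction"] == "up"])
planted = set(truth.de_proteins)

print(f"tested proteins: {len(table)}")
print(f"planted up-regulated proteins: {len(planted)}")
print(f"called up-regulated: {len(called)}")
print(f"recall: {len(called & planted) / len(planted):.2f}")
print(f"false discoveries among calls: {len(called - planted)}")
print("high recall with few false calls shows the paired design plus BH "
      "thresholds recover the planted biology")
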