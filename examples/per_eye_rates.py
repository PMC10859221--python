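"""Per-eye rates of change: OLS slopes and permutation classification.

Fits a regression of thickness on time for every eye's global RNFL and
MRW series of a simulated cohort, classifies each series by the SLR
p < .05 rule and by the permutation 2.5/97.5 percentile rule, and
compares the flag counts.
"""

from octtrend import (
    apply_eligibility,
    cohort_permutation_table,
    default_study_config,
    fit_all,
    generate_cohort,
    to_series,
)

design, params = default_study_config(seed=7)
cohort, _ = generate_cohort(design, params)
cohort, summary, _ = apply_eligibility(cohort)
series = [s for s in to_series(cohort) if s.sector == "G"]

fits = fit_all(series, alpha=0.05)
perm = cohort_permutation_table(series, n_perm=1000, seed=7)

for measure in ("RNFL", "MRW"):
    f = fits[fits["measure"] == measure]
    p = perm[perm["measure"] == measure]
    print(f"{measure}: median slope {f['slope'].median():+.2f} um/y | "
          f"SLR worsening {(f['label_slr'] == 'worsening').sum()}/{len(f)} | "
          f"permutation worsening {(p['label_perm'] == 'worsening').sum()}/{len(p)}")

print(
    "\nA 'worsening' eye has a significantly negative rate of change;"
    "\nthe permutation rule controls type-I error without assuming"
    "\nGaussian residuals."
)
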