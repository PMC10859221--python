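"""Longitudinal signal-to-noise: which measure detects change better?

Computes each eye's LSNR (OLS slope / OLS residual SD) for global RNFL
and MRW, compares the paired values with a Wilcoxon signed-rank test,
and compares the worsening-flag proportions with McNemar's test.
"""

from octtrend import (
    apply_eligibility,
    compare_lsnr_by_sector,
    default_study_config,
    fit_all,
    generate_cohort,
    lsnr_table,
    mcnemar_paired,
    to_series,
)

design, params = default_study_config(seed=7)
cohort, _ = generate_cohort(design, params)
cohort, _, _ = apply_eligibility(cohort)
series = [s for s in to_series(cohort) if s.sector == "G"]

fits = fit_all(series)
lsnr = lsnr_table(fits)
wilcoxon = compare_lsnr_by_sector(lsnr).iloc[0]
print(
    f"global LSNR medians: RNFL {wilcoxon['median_lsnr_rnfl']:+.3f} vs "
    f"MRW {wilcoxon['median_lsnr_mrw']:+.3f} "
    f"(Wilcoxon p = {wilcoxon['p']:.2g}, n = {wilcoxon['n_pairs']})"
)

mcn = mcnemar_paired(fits[["eye_id", "measure", "sector", "label_slr"]], "G", "worsening")
print(
    f"worsening flags, RNFL-only {mcn.b} vs MRW-only {mcn.c} eyes "
    f"(McNemar {mcn.method} p = {mcn.p_two_sided:.2g})"
)

print(
    "\nA more negative LSNR means the declining trend is larger relative"
    "\nto the series' own noise; with the default calibration RNFL series"
    "\nare less noisy per micrometre of change than MRW."
)
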