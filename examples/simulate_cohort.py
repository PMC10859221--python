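"""Generate a synthetic study cohort and inspect its design.

Builds a 113-eye cohort with the default calibrated design (6-monthly
visits, truncated-normal follow-up, session exclusions) and hierarchical
linear RNFL/MRW trajectories, then prints the realized design summary.
"""

from octtrend import default_study_config, generate_cohort, summarize_cohort

design, params = default_study_config(seed=7)
cohort, truth = generate_cohort(design, params)

print(cohort.head(6).to_string(index=False))
print(f"\nobservations: {len(cohort)}  "
      f"(eyes x sessions x 2 measures x 7 sectors, incl. excluded sessions)")

s = summarize_cohort(cohort)
print(
    f"\nanalyzed design: {s.n_eyes} eyes; "
    f"follow-up {s.mean_followup_years:.1f} +/- {s.sd_followup_years:.1f} y; "
    f"sessions median {s.median_sessions:.0f} (range {s.min_sessions}-{s.max_sessions})"
)
print(
    "\nThe summary describes usable (non-excluded) sessions; it should sit"
    "\nnear the calibration targets: ~5.2 y mean follow-up, median 10 scans."
)
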