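# Methods

This note records the statistical model behind `octtrend`, the
calibration of the synthetic cohort generator, and the numerical and
design choices a maintainer would want to know. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

The atomic record is one thickness value (μm) for one eye, imaging
session, measure (RNFL or MRW) and sector (G, T, ST, SN, N, IN, IT).
Time is real-valued years since the eye's first included session; ISO
dates in input files are converted at 365.25 days/year. Exclusion is
session-level: when a session is excluded (in the study design this
corresponds to a failed quality review), both measures and all sectors
of that session are dropped together. Eligibility mirrors the target
study design: an eye needs at least 3 usable sessions spanning at least
1.5 years (18 months). Analysis series are re-anchored so each starts at
t = 0; repeated same-day scans are tolerated but a regression series
needs ≥ 3 distinct times. One eye per patient is assumed throughout; no
intra-patient correlation is modelled.

## Per-eye regression and classification

Per series, ordinary least squares of y on t in closed form. The
residual SD uses denominator n − 2; the slope p-value is two-sided from
the t distribution with n − 2 df. Perfect lines (zero residual
variance, detected at RSS ≤ 1e−24 · max(‖y‖², 1)) are flagged
`degenerate` with the convention p = 0 for a nonzero slope and p = 1
for a zero slope, so exact fixtures remain usable; degenerate fits are
excluded pairwise from LSNR comparisons.

The permutation classifier permutes the raw y-values of each series
against its fixed times (the standard series-permutation null;
residual-permutation variants are out of scope) and recomputes the OLS
slope per permutation. With n! ≤ n_perm the n! orderings are enumerated
and p is a pure rank fraction; otherwise n_perm i.i.d. uniform
permutations are drawn and both tail p-values use the +1 correction, so
p ≥ 1/(n_perm + 1) and the test is conservative. Ties count inclusively
on both sides, with a 1e−9 relative tolerance absorbing float
summation-order differences between analytically equal slopes. A series
is worsening when p_lower ≤ 0.025 and improving when p_upper ≤ 0.025;
each eye is judged against its own null, not a pooled cohort null. Two
documented consequences: exhaustive mode is deterministic and ignores
the seed, and a series with n ≤ 4 can never be flagged (min p = 1/24).
Sampled mode refuses n_perm < 100 (unstable tails). The null is
exchangeability, so autocorrelated noise is outside the guarantee.

## Mixed model

Per measure × sector, the random intercept-and-slope model with an
unstructured 2×2 random-effect covariance (the least restrictive
choice) is fit by REML — the standard estimator when variance components
are themselves reported. The backend is statsmodels `MixedLM`; the fit
is retried across four optimizers (lbfgs, bfgs, cg, powell) before
reporting `converged=False` with no silent fallback. SDs of the random
effects are square roots of the estimated variances; their SEs use the
delta method, se(σ̂) = se(σ̂²)/(2σ̂), from the variance-parameter
covariance. Because the SE method for the random-effect SDs is a
convention (profile likelihood would be an alternative), only the point
estimates are treated as recovery targets. Variance estimates below
1e−6 × residual variance are flagged `boundary`. Data forming an exact
line defeat REML numerically and are returned directly as the boundary
solution they converge to: the pooled OLS line with all variance
components zero.

## Signal-to-noise and paired comparisons

LSNR = OLS slope / OLS residual SD, unitless per year, invariant to
rescaling the thickness axis — the property that makes RNFL and MRW
comparable despite different dynamic ranges. Paired comparisons use the
two-sided Wilcoxon signed-rank test on per-eye differences within a
sector; zero differences are dropped (Wilcoxon's original convention —
documented because small-n results depend on it), the null is exact for
≤ 25 non-zero differences without ties and a tie-corrected normal
approximation otherwise, and pairs with a degenerate member are dropped
pairwise. McNemar's test on flagged-vs-not dichotomies uses the exact
two-sided binomial p = min(1, 2·P(X ≤ min(b,c); b+c, ½)) below 25
discordant pairs and the continuity-corrected χ², (|b−c|−1)²/(b+c),
above. Worsening and improving are tested as separate dichotomies. No
multiplicity correction is applied across sectors (sector-wise p-values
are reported unadjusted).

## Synthetic cohort generator

Trajectories are hierarchical linear: y_ij = (β₀+b₀ᵢ) + (β₁+b₁ᵢ)t_ij +
ε_ij with (b₀,b₁) bivariate normal between eyes and ε i.i.d. Gaussian.
`default_study_config` sets β₀, β₁ and the between-eye SDs per measure
and sector to published mixed-model estimates for a
moderate-to-advanced glaucoma cohort (global RNFL: 62.8 ± 13.9 μm,
−0.64 ± 0.75 μm/y; global MRW: 159.6 ± 50.7 μm, −1.10 ± 2.39 μm/y; and
analogously for the six sectors).

Choices where the calibration source is silent, all overridable:

- **Residual SDs** (within-eye): 2.0 μm (RNFL) and 6.0 μm (MRW) per
  sector. Cross-checked: at 113 eyes these imply population-slope SEs of
  ≈ 0.08 (RNFL global) and ≈ 0.25 (MRW global) μm/y, matching the
  reported SEs; they also make MRW series noisier than RNFL at
  comparable slopes, the mechanism behind the LSNR contrast.
- **Correlations**: corr(b₀,b₁) = 0 within a measure; the RNFL and MRW
  random slopes of the same eye and sector are coupled with correlation
  0.3. Both are free knobs, not claims.
- **Visit schedule**: t₀ = 0, increments Normal(0.5, 0.1) years rejected
  below 0.1 y, and the final visit placed at the eye's drawn follow-up
  duration, so the drawn duration is the realized span.
- **Follow-up distribution**: parent Normal(6.9, 1.75) years, truncated
  by rejection to [1.6, 6.7]. The parent values are calibrated so the
  *analyzed* cohort (after session exclusions) reproduces the design
  targets: ≈ 5.2 y mean follow-up and a median of 10 usable sessions.
  A known limitation of this mechanism: on [1.6, 6.7] the truncated
  normal family cannot simultaneously hit mean 5.2 and SD 1.3, so the
  realized follow-up SD is ≈ 1.05 y, somewhat tighter than the target
  design's 1.3 y.
- **Session exclusions**: each session is independently unusable with
  p = 0.17, a combined missed-visit + quality-failure rate calibrated
  jointly with the follow-up parent to the session-count target.
- **Floors**: thickness is censored from below at 1 μm always (it is a
  physical quantity; without this, the largest between-eye SDs would
  occasionally produce negative values — this binds on well under 1% of
  observations in the most extreme MRW sectors). A measurement floor in
  the clinical sense is off by default; `advanced_damage_config` sets an
  RNFL floor of 50 μm as a documented convention to exercise censoring.
- **Reproducibility**: each eye draws from an RNG substream keyed by
  (seed, eye index) in a fixed order (follow-up, visit increments,
  exclusion flags, per-sector effects, noise), so enlarging a cohort
  never perturbs existing eyes and equal seeds give byte-identical
  cohorts.

What the generator does *not* emulate: nonlinear trajectories (the
analysis model itself assumes linearity), within-eye autocorrelated
noise, informative dropout (follow-up is independent of trajectory),
fellow-eye correlation, and floor effects by default. Passing recovery
tests therefore show the estimators are correct *under the assumed
model*, not that real cohorts satisfy those assumptions — which is
exactly what the empirical-residual window diagnostic is for in real
data.

## Diagnostics and pipeline

Empirical residuals are y minus the series' own follow-up mean,
summarized in half-open windows [0,3), [3,9), [9,15), … months
(months = 12·t). Residuals are averaged within eye-window first, then
across eyes, so frequently-scanned eyes do not dominate; the SE is the
between-eye standard error; empty windows are omitted rather than
zero-filled. `run_pipeline` chains all stages with a fixed seed policy
(per-series permutation streams derived from (seed, eye, measure,
sector)), writes one CSV per stage plus a manifest with a config hash,
removes partial outputs on failure, and tags errors with the failing
stage. Outputs are a pure function of (input, config, seed).

## Verification experiment sizes

The recovery experiment uses 20 replicate cohorts of 113 eyes (ensemble
SEs ≈ 0.02 μm/y for the RNFL global slope, ≈ 0.05 for MRW), the
permutation type-I experiment 2,000 null series of 10 visits at
n_perm = 1000 in the test suite and 10,000 in the reproduction script,
and the calibration check 10 seeds; together about a minute of compute.
A sizing note on the type-I experiment: with n_perm = 1000 and the +1
correction, a tail flag requires the observed slope to rank ≤ 25 among
1001 exchangeable values, so the exact two-sided level is
2·25/1001 ≈ 0.04995 — essentially at the nominal 0.05. The flag-rate
estimate therefore needs enough series that its Monte-Carlo error
(SE ≈ 0.005 at 2,000, ≈ 0.002 at 10,000) is read as precision around
0.05, not as evidence of anti-conservatism.
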