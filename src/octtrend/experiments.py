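"""Simulation experiments verifying the pipeline against known truth.

These reusable experiments back the package's validation story: mixed-
model parameter recovery on replicate synthetic cohorts, the empirical
type-I error of the permutation classifier under a null of no change,
and the calibration of the default study design. They are what the test
suite and the reproduction script run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortSummary, apply_eligibility, summarize_cohort, to_series, EyeSeries
from .lmm import fit_lmm
from .permutation import classify_permutation
from .simulate import default_study_config, generate_cohort
from .slr import STABLE


def lmm_recovery_ensemble(
    seeds, sector: str = "G", measures=("RNFL", "MRW")
) -> pd.DataFrame:
    """Fit the random intercept-and-slope model to replicate cohorts.

    For each seed, a full default-design cohort is generated, eligibility
    is applied, and the LMM is fit per measure for the given sector.
    Returns one row per (seed, measure) with the estimated population
    slope and random-slope SD alongside the generating truth.
    """
    rows = []
    for seed in seeds:
        design, params = default_study_config(seed=int(seed))
        cohort, _ = generate_cohort(design, params)
        cohort, _, _ = apply_eligibility(cohort)
        series = to_series(cohort)
        for measure in measures:
            sub = [s for s in series if s.measure == measure and s.sector == sector]
            fit = fit_lmm(sub)
            p = params[(measure, sector)]
            rows.append(
                {
                    "seed": int(seed),
                    "measure": measure,
                    "sector": sector,
                    "slope_est": fit.beta1_um_per_year,
                    "slope_sd_est": fit.sd_b1,
                    "slope_truth": p.beta1_um_per_year,
                    "slope_sd_truth": p.sd_b1,
                    "n_eyes": fit.n_eyes,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def ensemble_recovery_check(ensemble: pd.DataFrame, column: str) -> dict:
    """Ensemble mean of an estimate vs truth, in ensemble-SE units.

    ``column`` is ``slope`` or ``slope_sd``. The ensemble SE is the SD of
    the per-cohort estimates divided by sqrt(#cohorts).
    """
    est = ensemble[f"{column}_est"].to_numpy(dtype=float)
    truth = float(ensemble[f"{column}_truth"].iloc[0])
    mean = float(est.mean())
    se = float(est.std(ddof=1) / np.sqrt(len(est)))
    return {
        "mean": mean,
        "truth": truth,
        "ensemble_se": se,
        "n_cohorts": len(est),
        "z": (mean - truth) / se if se > 0 else np.inf,
        "within_2se": abs(mean - truth) <= 2 * se,
    }


def permutation_null_rate(
    n_series: int = 2000,
    n_visits: int = 10,
    interval_years: float = 0.5,
    sigma_um: float = 2.0,
    n_perm: int = 1000,
    seed: int = 0,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> float:
    """Two-sided flag rate of the permutation classifier under no change.

    Simulates ``n_series`` independent series with a true slope of zero
    and i.i.d. Gaussian noise on a regular visit grid, classifies each
    against its own permutation null, and returns the fraction flagged
    (worsening or improving).
    """
    t = np.arange(n_visits) * interval_years
    rng = np.random.default_rng([seed, 91])
    flagged = 0
    for i in range(n_series):
        y = 60.0 + rng.normal(0.0, sigma_um, n_visits)
        s = EyeSeries(f"null{i}", "RNFL", "G", t, y)
        r = classify_permutation(
            s, n_perm=n_perm, seed=[seed, 91, i], lower_pct=lower_pct, upper_pct=upper_pct
        )
        flagged += r.label != STABLE
    return flagged / n_series


def design_calibration(seeds) -> list[CohortSummary]:
    """Cohort summaries of default-design cohorts across seeds."""
    out = []
    for seed in seeds:
        design, params = default_study_config(seed=int(seed))
        cohort, _ = generate_cohort(design, params)
        out.append(summarize_cohort(cohort))
    return out
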