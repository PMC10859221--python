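"""Per-series simple linear regression of thickness on time.

Each eye x measure x sector series is fit by ordinary least squares,
giving the rate of change (slope, micrometres/year), its standard error,
a two-sided p-value from the t distribution with n - 2 degrees of
freedom, and the residual SD (denominator n - 2) that later feeds the
longitudinal signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import EyeSeries
from .exceptions import IdentifiabilityError, ParameterError

WORSENING = "worsening"
STABLE = "stable"
IMPROVING = "improving"


@dataclass(frozen=True)
class SlrFit:
    """Ordinary-least-squares fit of one series.

    ``degenerate`` marks zero-residual-variance fits (perfect lines),
    where the sampling distribution of the slope collapses: by convention
    p = 0 for a nonzero slope and p = 1 for a zero slope.
    """

    slope_um_per_year: float
    intercept_um: float
    slope_se: float
    p_two_sided: float
    residual_sd_um: float
    n: int
    degenerate: bool = False
    eye_id: str | None = None
    measure: str | None = None
    sector: str | None = None


def fit_slr(series: EyeSeries) -> SlrFit:
    """Closed-form least squares of y (um) on t (years)."""
    t, y = series.t, series.y
    n = len(t)
    if n < 3:
        raise IdentifiabilityError("need at least 3 observations")
    tc = t - t.mean()
    sxx = float(tc @ tc)
    if sxx == 0.0:
        raise IdentifiabilityError("all time points identical")
    slope = float(tc @ y) / sxx
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    rss = float(resid @ resid)
    # guard tiny negative / roundoff RSS on perfect lines
    scale = max(float(y @ y), 1.0)
    if rss <= 1e-24 * scale:
        p = 1.0 if slope == 0.0 else 0.0
        return SlrFit(
            slope, intercept, 0.0, p, 0.0, n, degenerate=True,
            eye_id=series.eye_id, measure=series.measure, sector=series.sector,
        )
    residual_sd = np.sqrt(rss / (n - 2))
    slope_se = residual_sd / np.sqrt(sxx)
    tstat = slope / slope_se
    p = 2.0 * float(stats.t.sf(abs(tstat), df=n - 2))
    return SlrFit(
        slope, intercept, float(slope_se), p, float(residual_sd), n,
        eye_id=series.eye_id, measure=series.measure, sector=series.sector,
    )


def classify_slr(fit: SlrFit, alpha: float = 0.05) -> str:
    """Label a fit worsening/stable/improving at significance ``alpha``.

    Worsening means a significantly negative rate of change (p < alpha),
    improving a significantly positive one.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if fit.p_two_sided < alpha:
        if fit.slope_um_per_year < 0:
            return WORSENING
        if fit.slope_um_per_year > 0:
            return IMPROVING
    return STABLE


def fit_all(series_list: list[EyeSeries], alpha: float = 0.05) -> pd.DataFrame:
    """Fit every series; failures are recorded per series, never raised.

    Returns a frame keyed by (eye_id, measure, sector) with the fit
    fields, the significance label under the SLR p < alpha criterion, and
    an ``error`` column (empty string when the fit succeeded). Output is
    sorted by key, independent of input order.
    """
    if not series_list:
        raise ParameterError("empty series collection")
    rows = []
    for s in sorted(series_list, key=lambda s: s.key):
        try:
            f = fit_slr(s)
            rows.append(
                {
                    "eye_id": s.eye_id,
                    "measure": s.measure,
                    "sector": s.sector,
                    "n": f.n,
                    "slope": f.slope_um_per_year,
                    "intercept": f.intercept_um,
                    "slope_se": f.slope_se,
                    "p": f.p_two_sided,
                    "residual_sd": f.residual_sd_um,
                    "degenerate": f.degenerate,
                    "label_slr": classify_slr(f, alpha),
                    "error": "",
                }
            )
        except IdentifiabilityError as exc:
            rows.append(
                {
                    "eye_id": s.eye_id,
                    "measure": s.measure,
                    "sector": s.sector,
                    "n": len(s.t),
                    "slope": np.nan,
                    "intercept": np.nan,
                    "slope_se": np.nan,
                    "p": np.nan,
                    "residual_sd": np.nan,
                    "degenerate": False,
                    "label_slr": "",
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
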