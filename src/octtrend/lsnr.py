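"""Longitudinal signal-to-noise ratios and paired Wilcoxon comparison.

The LSNR of a series is its OLS rate of change divided by the OLS
residual SD — a unitless (per year) measure of how large the trend is
relative to the measurement noise around it, comparable across metrics
with different dynamic ranges. Per sector, the paired per-eye LSNRs of
the two measures are compared with a two-sided Wilcoxon signed-rank
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .slr import SlrFit

# exact signed-rank null up to this many non-zero differences; the
# tie-corrected normal approximation beyond
EXACT_MAX_N = 25


@dataclass(frozen=True)
class LsnrValue:
    """LSNR of one series; ``degenerate`` flags zero-residual fits."""

    eye_id: str | None
    measure: str | None
    sector: str | None
    lsnr: float
    degenerate: bool


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon signed-rank comparison of paired per-eye values."""

    n_pairs: int
    n_nonzero: int
    statistic: float
    p_two_sided: float
    method: str
    no_information: bool = False


def compute_lsnr(fit: SlrFit) -> LsnrValue:
    """slope / residual SD; degenerate (value withheld) when residual SD = 0."""
    if fit.residual_sd_um == 0.0:
        return LsnrValue(fit.eye_id, fit.measure, fit.sector, np.nan, True)
    return LsnrValue(
        fit.eye_id,
        fit.measure,
        fit.sector,
        fit.slope_um_per_year / fit.residual_sd_um,
        False,
    )


def lsnr_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-series LSNR from a fit table (as produced by slr.fit_all)."""
    out = fits.loc[fits["error"] == "", ["eye_id", "measure", "sector"]].copy()
    ok = fits["error"] == ""
    rsd = fits.loc[ok, "residual_sd"].to_numpy()
    slope = fits.loc[ok, "slope"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["lsnr"] = np.where(rsd > 0, slope / rsd, np.nan)
    out["degenerate"] = rsd == 0
    return out.reset_index(drop=True)


def compare_lsnr(
    lsnr_a: np.ndarray, lsnr_b: np.ndarray
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences a - b.

    Pairs with a non-finite member (degenerate fits) are dropped, as are
    zero differences (Wilcoxon's original convention). The null
    distribution is exact for up to 25 non-zero untied differences and a
    tie-corrected normal approximation otherwise. With no informative
    pairs the result carries p = 1 and the no-information flag.
    """
    a = np.asarray(lsnr_a, dtype=float)
    b = np.asarray(lsnr_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    d = a[keep] - b[keep]
    n_pairs = int(keep.sum())
    d_nz = d[d != 0]
    n_nonzero = len(d_nz)
    if n_nonzero == 0:
        return PairedTestResult(n_pairs, 0, np.nan, 1.0, "none", True)
    ties = len(np.unique(np.abs(d_nz))) < n_nonzero
    if n_nonzero <= EXACT_MAX_N and not ties:
        method = "exact"
        res = stats.wilcoxon(d_nz, zero_method="wilcox", method="exact")
    else:
        method = "approx"
        res = stats.wilcoxon(
            d_nz, zero_method="wilcox", method="approx", correction=False
        )
    return PairedTestResult(
        n_pairs, n_nonzero, float(res.statistic), float(res.pvalue), method
    )


def compare_lsnr_by_sector(lsnr: pd.DataFrame) -> pd.DataFrame:
    """Sector-wise paired RNFL-vs-MRW Wilcoxon tests from an LSNR table.

    Eyes are paired within sector; pairs where either measure's fit is
    degenerate are dropped. Returns one row per sector with the test and
    the median LSNR of each measure among the compared pairs.
    """
    rows = []
    for sector, g in lsnr.groupby("sector", sort=True):
        wide = g.pivot(index="eye_id", columns="measure", values="lsnr")
        if not {"RNFL", "MRW"} <= set(wide.columns):
            continue
        r = wide["RNFL"].to_numpy()
        m = wide["MRW"].to_numpy()
        res = compare_lsnr(r, m)
        ok = np.isfinite(r) & np.isfinite(m)
        rows.append(
            {
                "sector": sector,
                "n_pairs": res.n_pairs,
                "n_nonzero": res.n_nonzero,
                "statistic": res.statistic,
                "p": res.p_two_sided,
                "method": res.method,
                "median_lsnr_rnfl": float(np.median(r[ok])) if ok.any() else np.nan,
                "median_lsnr_mrw": float(np.median(m[ok])) if ok.any() else np.nan,
            }
        )
    if not rows:
        raise ParameterError("no sector with both measures present")
    return pd.DataFrame(rows)
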