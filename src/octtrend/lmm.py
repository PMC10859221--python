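"""Random intercept-and-slope linear mixed model per measure x sector.

Fits y_ij = (beta0 + b0_i) + (beta1 + b1_i) t_ij + eps_ij by REML with an
unstructured 2x2 random-effect covariance (statsmodels MixedLM backend),
reporting population intercept/slope with model-based SEs and the
between-eye random-effect SDs with delta-method SEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .cohort import EyeSeries, MEASURES, SECTORS
from .exceptions import ParameterError

#  random-effect variance below this fraction of the residual variance is
#  reported as a boundary (variance -> 0) fit
_BOUNDARY_REL_TOL = 1e-6
#  pooled residual SD below this (um) means the data are an exact line
_EXACT_LINE_TOL = 1e-8

#  report rows follow the conventional table order: RNFL block then MRW,
#  sectors global, temporal, superotemporal, inferotemporal, nasal,
#  superonasal, inferonasal
REPORT_SECTOR_ORDER = ("G", "T", "ST", "IT", "N", "SN", "IN")


@dataclass(frozen=True)
class LmmFit:
    """Population and variance-component estimates for one measure x sector."""

    beta0_um: float
    beta0_se: float
    beta1_um_per_year: float
    beta1_se: float
    sd_b0: float
    sd_b0_se: float
    sd_b1: float
    sd_b1_se: float
    corr_b0_b1: float
    sigma_resid_um: float
    n_eyes: int
    n_obs: int
    converged: bool
    boundary: bool = False


def _stack(series_list: list[EyeSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        rows.append(pd.DataFrame({"eye_id": s.eye_id, "t": s.t, "y": s.y}))
    return pd.concat(rows, ignore_index=True)


def fit_lmm(series_list: list[EyeSeries]) -> LmmFit:
    """REML fit of the random intercept-and-slope model.

    ``series_list`` must contain one series per eye for a single measure
    and sector. Non-convergence after retries is reported through
    ``converged=False``, never silently replaced by another model.
    """
    if not series_list:
        raise ParameterError("empty series collection")
    eyes = {s.eye_id for s in series_list}
    if len(eyes) < 2:
        raise ParameterError("need series from at least 2 eyes")
    if len(eyes) != len(series_list):
        raise ParameterError("expected exactly one series per eye")

    df = _stack(series_list)
    n_eyes, n_obs = len(eyes), len(df)

    # exact-line data (zero residual variance) defeats REML numerically;
    # fall back to the closed form it converges to: pooled OLS line with
    # all variance components at the zero boundary
    pooled = np.polyfit(df["t"], df["y"], 1)
    resid = df["y"] - np.polyval(pooled, df["t"])
    if float(np.sqrt(np.mean(resid**2))) < _EXACT_LINE_TOL:
        return LmmFit(
            beta0_um=float(pooled[1]), beta0_se=0.0,
            beta1_um_per_year=float(pooled[0]), beta1_se=0.0,
            sd_b0=0.0, sd_b0_se=0.0, sd_b1=0.0, sd_b1_se=0.0,
            corr_b0_b1=0.0, sigma_resid_um=0.0,
            n_eyes=n_eyes, n_obs=n_obs, converged=True, boundary=True,
        )

    exog = sm.add_constant(df[["t"]])
    model = MixedLM(df["y"], exog, groups=df["eye_id"], exog_re=exog)
    result = None
    attempts = (
        {"method": "lbfgs"},
        {"method": "bfgs"},
        {"method": "cg"},
        {"method": "powell"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for kw in attempts:
            try:
                cand = model.fit(reml=True, **kw)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand.converged and np.isfinite(cand.fe_params).all():
                result = cand
                break
            if result is None:
                result = cand

    if result is None:
        return LmmFit(
            *(np.nan,) * 10, n_eyes=n_eyes, n_obs=n_obs,
            converged=False, boundary=False,
        )

    cov_re = np.asarray(result.cov_re)
    scale = float(result.scale)
    var0, var1 = float(cov_re[0, 0]), float(cov_re[1, 1])
    sd0, sd1 = np.sqrt(max(var0, 0.0)), np.sqrt(max(var1, 0.0))
    corr = float(cov_re[0, 1] / (sd0 * sd1)) if sd0 > 0 and sd1 > 0 else 0.0
    corr = float(np.clip(corr, -1.0, 1.0))
    boundary = min(var0, var1) < _BOUNDARY_REL_TOL * scale

    # delta method: se(sd) = se(var) / (2 sd); bse_re is on the cov_re scale
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            bse_re = np.asarray(result.bse_re)
            se_var0, se_var1 = float(bse_re[0]), float(bse_re[2])
        except (ValueError, np.linalg.LinAlgError):
            se_var0 = se_var1 = np.nan
    sd0_se = se_var0 / (2 * sd0) if sd0 > 0 and np.isfinite(se_var0) else np.nan
    sd1_se = se_var1 / (2 * sd1) if sd1 > 0 and np.isfinite(se_var1) else np.nan

    return LmmFit(
        beta0_um=float(result.fe_params.iloc[0]),
        beta0_se=float(result.bse_fe.iloc[0]),
        beta1_um_per_year=float(result.fe_params.iloc[1]),
        beta1_se=float(result.bse_fe.iloc[1]),
        sd_b0=float(sd0),
        sd_b0_se=sd0_se,
        sd_b1=float(sd1),
        sd_b1_se=sd1_se,
        corr_b0_b1=corr,
        sigma_resid_um=float(np.sqrt(scale)),
        n_eyes=n_eyes,
        n_obs=n_obs,
        converged=bool(result.converged),
        boundary=bool(boundary),
    )


def fit_lmm_by_group(series_list: list[EyeSeries]) -> dict[tuple[str, str], LmmFit]:
    """Fit one LMM per (measure, sector) present in the collection."""
    groups: dict[tuple[str, str], list[EyeSeries]] = {}
    for s in series_list:
        groups.setdefault((s.measure, s.sector), []).append(s)
    return {key: fit_lmm(sl) for key, sl in sorted(groups.items())}


def lmm_report(fits: dict[tuple[str, str], LmmFit]) -> pd.DataFrame:
    """Tabular report, one row per measure x sector.

    Rows are ordered RNFL block then MRW, sectors in the conventional
    order (G, T, ST, IT, N, SN, IN); estimate/SE pairs for population
    intercept, intercept SD, population slope and slope SD, plus residual
    SD and the intercept-slope correlation.
    """
    if not fits:
        raise ParameterError("no fits to report")
    rows = []
    for measure in MEASURES:
        for sector in REPORT_SECTOR_ORDER:
            f = fits.get((measure, sector))
            if f is None:
                continue
            rows.append(
                {
                    "measure": measure,
                    "sector": sector,
                    "intercept": f.beta0_um,
                    "intercept_se": f.beta0_se,
                    "intercept_sd": f.sd_b0,
                    "intercept_sd_se": f.sd_b0_se,
                    "slope": f.beta1_um_per_year,
                    "slope_se": f.beta1_se,
                    "slope_sd": f.sd_b1,
                    "slope_sd_se": f.sd_b1_se,
                    "sigma_resid": f.sigma_resid_um,
                    "corr_b0_b1": f.corr_b0_b1,
                    "n_eyes": f.n_eyes,
                    "n_obs": f.n_obs,
                    "converged": f.converged,
                    "boundary": f.boundary,
                }
            )
    # any non-standard keys (defensive) appended after the canonical blocks
    std = {(m, s) for m in MEASURES for s in SECTORS}
    for key in sorted(fits):
        if key not in std:
            raise ParameterError(f"unknown measure/sector key {key!r}")
    return pd.DataFrame(rows)
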