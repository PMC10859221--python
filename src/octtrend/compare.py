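"""Cohort-level progression proportions and McNemar paired comparison.

For each measure and sector, the fraction of eyes flagged worsening or
improving under a stated criterion (SLR p < alpha, or permutation
percentile cutoffs) is tabulated; per sector and direction, the paired
agreement of the two measures across the same eyes is tested with
McNemar's test on the discordant counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .slr import IMPROVING, WORSENING

# exact binomial McNemar below this many discordant pairs, the
# continuity-corrected chi-square at or above it
EXACT_MAX_DISCORDANT = 25


@dataclass(frozen=True)
class McNemarResult:
    """Paired comparison of flag proportions between the two measures.

    ``b`` counts eyes flagged for the first measure only, ``c`` those
    flagged for the second only.
    """

    b: int
    c: int
    p_two_sided: float
    method: str
    no_discordance: bool = False


def mcnemar_from_counts(b: int, c: int) -> McNemarResult:
    """McNemar's test from discordant-pair counts.

    Exact two-sided binomial p = min(1, 2 P(X <= min(b, c); n = b + c,
    1/2)) when b + c < 25; otherwise the chi-square approximation with
    continuity correction, (|b - c| - 1)^2 / (b + c) on 1 df.
    """
    if b < 0 or c < 0:
        raise ParameterError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(0, 0, 1.0, "exact", no_discordance=True)
    if n < EXACT_MAX_DISCORDANT:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
        return McNemarResult(b, c, p, "exact")
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(b, c, p, "chi2_cc")


def _label_column(labels: pd.DataFrame, criterion: str) -> str:
    col = {"slr_p": "label_slr", "permutation": "label_perm"}.get(criterion)
    if col is None:
        raise ParameterError(f"unknown criterion {criterion!r}")
    if col not in labels.columns:
        raise ParameterError(f"labels table lacks column {col!r}")
    return col


def tabulate_proportions(labels: pd.DataFrame, criterion: str) -> pd.DataFrame:
    """Worsening/improving counts and percentages per measure x sector.

    ``labels`` holds one row per (eye_id, measure, sector) with a label
    column for the chosen criterion (``slr_p`` or ``permutation``).
    Every eye present for one measure in a sector must be present for the
    other measures of that sector (paired design).
    """
    col = _label_column(labels, criterion)
    lab = labels.loc[labels[col] != ""]
    for sector, g in lab.groupby("sector"):
        eyes_by_measure = {
            m: set(gg["eye_id"]) for m, gg in g.groupby("measure")
        }
        sets = list(eyes_by_measure.values())
        if any(s != sets[0] for s in sets[1:]):
            raise ParameterError(
                f"sector {sector}: eyes differ between measures (pairing broken)"
            )
    rows = []
    for (measure, sector), g in lab.groupby(["measure", "sector"], sort=True):
        n = len(g)
        nw = int((g[col] == WORSENING).sum())
        ni = int((g[col] == IMPROVING).sum())
        rows.append(
            {
                "measure": measure,
                "sector": sector,
                "criterion": criterion,
                "n_series": n,
                "n_worsening": nw,
                "n_improving": ni,
                "pct_worsening": 100.0 * nw / n,
                "pct_improving": 100.0 * ni / n,
            }
        )
    return pd.DataFrame(rows)


def mcnemar_paired(
    labels: pd.DataFrame,
    sector: str,
    direction: str,
    criterion: str = "slr_p",
    measures: tuple[str, str] = ("RNFL", "MRW"),
) -> McNemarResult:
    """McNemar's test comparing flag rates of two measures in one sector.

    ``direction`` is ``worsening`` or ``improving``; each eye contributes
    one paired dichotomy (flagged vs not) per measure.
    """
    if direction not in (WORSENING, IMPROVING):
        raise ParameterError(f"direction must be worsening|improving, got {direction!r}")
    col = _label_column(labels, criterion)
    g = labels.loc[(labels["sector"] == sector) & (labels[col] != "")]
    wide = g.pivot(index="eye_id", columns="measure", values=col)
    for m in measures:
        if m not in wide.columns:
            raise ParameterError(f"no labels for measure {m} in sector {sector}")
    if wide[list(measures)].isna().any().any():
        raise ParameterError(
            f"sector {sector}: some eyes lack a label for one measure"
        )
    fa = wide[measures[0]] == direction
    fb = wide[measures[1]] == direction
    b = int((fa & ~fb).sum())
    c = int((~fa & fb).sum())
    return mcnemar_from_counts(b, c)


def mcnemar_table(
    labels: pd.DataFrame, criterion: str = "slr_p"
) -> pd.DataFrame:
    """McNemar p per sector and direction (worsening, improving)."""
    rows = []
    for sector in sorted(labels["sector"].unique()):
        for direction in (WORSENING, IMPROVING):
            r = mcnemar_paired(labels, sector, direction, criterion)
            rows.append(
                {
                    "sector": sector,
                    "direction": direction,
                    "criterion": criterion,
                    "b_rnfl_only": r.b,
                    "c_mrw_only": r.c,
                    "p": r.p_two_sided,
                    "method": r.method,
                }
            )
    return pd.DataFrame(rows)
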