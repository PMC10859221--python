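"""Permutation null for per-series slopes and tail-based classification.

The null hypothesis of no change is represented by permuting each
series' thickness values against its fixed visit times and recomputing
the OLS slope. A series is flagged as significantly worsening when its
observed slope sits at or below the 2.5th-percentile tail of its own
permutation distribution, and improving at or above the 97.5th. For
short series (n! <= n_perm) the distribution is enumerated exhaustively;
otherwise it is sampled, and the sampled p-values use the +1 correction
(the observed ordering counts as one permutation), which keeps them
strictly positive and the test conservative.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .cohort import EyeSeries
from .exceptions import ParameterError
from .slr import IMPROVING, STABLE, WORSENING

_MIN_SAMPLED = 100


@dataclass(frozen=True)
class PermutationResult:
    """Classification of one series against its permutation null."""

    observed_slope: float
    n_perm: int
    exhaustive: bool
    p_lower: float
    p_upper: float
    q025: float
    q975: float
    label: str
    eye_id: str | None = None
    measure: str | None = None
    sector: str | None = None


def _slope_weights(t: np.ndarray) -> np.ndarray:
    tc = t - t.mean()
    sxx = float(tc @ tc)
    if sxx == 0.0:
        raise ParameterError("all time points identical; slope not identifiable")
    return tc / sxx


def permute_slopes(
    series: EyeSeries, n_perm: int = 1000, seed: int | None = 0
) -> np.ndarray:
    """Null slope distribution of one series.

    Exhaustive (all n! orderings, seed ignored) when n! <= n_perm;
    otherwise ``n_perm`` i.i.d. uniform random permutations.
    """
    slopes, _ = _null_slopes(series, n_perm, seed)
    return slopes


def _null_slopes(series, n_perm, seed):
    t = np.asarray(series.t, dtype=float)
    y = np.asarray(series.y, dtype=float)
    w = _slope_weights(t)
    n = len(t)
    if factorial(n) <= n_perm:
        perms = np.array(list(itertools.permutations(range(n))))
        return perms_dot(y, perms, w), True
    if n_perm < _MIN_SAMPLED:
        raise ParameterError(
            f"n_perm={n_perm} too small for sampled mode (min {_MIN_SAMPLED})"
        )
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    return perms_dot(y, perms, w), False


def perms_dot(y: np.ndarray, perms: np.ndarray, w: np.ndarray) -> np.ndarray:
    return y[perms] @ w


def classify_permutation(
    series: EyeSeries,
    n_perm: int = 1000,
    seed: int | None = 0,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> PermutationResult:
    """Classify one series by the tails of its permutation null.

    ``p_lower`` is the fraction of null slopes at or below the observed
    slope (with the +1 correction in sampled mode), ``p_upper`` the
    analogous upper-tail fraction. The label is worsening when
    ``p_lower <= lower_pct/100``, improving when
    ``p_upper <= (100 - upper_pct)/100``, else stable. The reported
    q025/q975 are diagnostic percentiles (linear interpolation) of the
    null slopes.
    """
    if lower_pct >= upper_pct:
        raise ParameterError("lower_pct must be < upper_pct")
    if not (0 < lower_pct < 100 and 0 < upper_pct < 100):
        raise ParameterError("percentile cutoffs must lie in (0, 100)")
    slopes, exhaustive = _null_slopes(series, n_perm, seed)
    w = _slope_weights(np.asarray(series.t, dtype=float))
    observed = float(np.asarray(series.y, dtype=float) @ w)
    m = len(slopes)
    add = 0 if exhaustive else 1
    # ties are counted inclusively (conservative); the tolerance absorbs
    # float summation-order differences between equal-slope orderings
    eps = 1e-9 * max(1.0, abs(observed), float(np.abs(slopes).max()))
    p_lower = (int(np.sum(slopes <= observed + eps)) + add) / (m + add)
    p_upper = (int(np.sum(slopes >= observed - eps)) + add) / (m + add)
    if p_lower <= lower_pct / 100.0:
        label = WORSENING
    elif p_upper <= (100.0 - upper_pct) / 100.0:
        label = IMPROVING
    else:
        label = STABLE
    q025, q975 = np.percentile(slopes, [2.5, 97.5])
    return PermutationResult(
        observed_slope=observed,
        n_perm=m,
        exhaustive=exhaustive,
        p_lower=p_lower,
        p_upper=p_upper,
        q025=float(q025),
        q975=float(q975),
        label=label,
        eye_id=series.eye_id,
        measure=series.measure,
        sector=series.sector,
    )


def _series_seed(seed: int, eye_id: str, measure: str, sector: str) -> list[int]:
    """Deterministic per-series RNG entropy from the run seed and the key."""
    tag = zlib.crc32(f"{eye_id}|{measure}|{sector}".encode())
    return [seed, tag]


def cohort_permutation_table(
    series_list: list[EyeSeries],
    n_perm: int = 1000,
    seed: int = 0,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> pd.DataFrame:
    """Permutation classification of every series in a cohort.

    Per-series RNG streams are derived from (seed, eye, measure, sector),
    so results do not depend on collection order.
    """
    if not series_list:
        raise ParameterError("empty series collection")
    rows = []
    for s in sorted(series_list, key=lambda s: s.key):
        r = classify_permutation(
            s,
            n_perm=n_perm,
            seed=_series_seed(seed, s.eye_id, s.measure, s.sector),
            lower_pct=lower_pct,
            upper_pct=upper_pct,
        )
        rows.append(
            {
                "eye_id": s.eye_id,
                "measure": s.measure,
                "sector": s.sector,
                "observed_slope": r.observed_slope,
                "n_perm": r.n_perm,
                "exhaustive": r.exhaustive,
                "p_lower": r.p_lower,
                "p_upper": r.p_upper,
                "q025": r.q025,
                "q975": r.q975,
                "label_perm": r.label,
            }
        )
    return pd.DataFrame(rows)
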