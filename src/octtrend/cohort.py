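"""Cohort data model, long-format CSV I/O, validation and eligibility filtering.

A *cohort* is a long-format :class:`pandas.DataFrame` with one row per
eye x session x measure x sector observation and the canonical columns

    eye_id, session_index, t_years, measure, sector, thickness_um,
    session_excluded

Time is expressed in years since each eye's first session; thickness in
micrometres. Two structural measures are supported — the circumpapillary
retinal nerve fiber layer (``RNFL``) and the Bruch membrane
opening-minimum rim width (``MRW``) — on the global region plus six
optic-nerve-head sectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    CohortValidationError,
    EmptyCohortError,
    LookupError_,
    SchemaError,
)

MEASURES = ("RNFL", "MRW")
#: global + 6 sectors: temporal, superotemporal, superonasal, nasal,
#: inferonasal, inferotemporal
SECTORS = ("G", "T", "ST", "SN", "N", "IN", "IT")

COHORT_COLUMNS = [
    "eye_id",
    "session_index",
    "t_years",
    "measure",
    "sector",
    "thickness_um",
    "session_excluded",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ThicknessObservation:
    """One thickness value for one eye/session/measure/sector."""

    eye_id: str
    session_index: int
    t_years: float
    measure: str
    sector: str
    thickness_um: float
    session_excluded: bool = False


@dataclass(frozen=True)
class EyeSeries:
    """Time-ordered (t, y) measurements for one eye x measure x sector.

    The unit of per-eye regression and permutation analysis. ``t`` is in
    years from the series' first included session (so ``t[0] == 0``), ``y``
    in micrometres.
    """

    eye_id: str
    measure: str
    sector: str
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.shape != y.shape or t.ndim != 1:
            raise CohortValidationError("t and y must be 1-d vectors of equal length")
        if len(t) < 3:
            raise CohortValidationError(
                f"series {self.key} has {len(t)} points; at least 3 required"
            )
        if np.any(np.diff(t) < 0):
            raise CohortValidationError(f"series {self.key} times not ascending")
        if len(np.unique(t)) < 3:
            raise CohortValidationError(
                f"series {self.key} needs >= 3 distinct time points"
            )

    @property
    def key(self) -> tuple:
        return (self.eye_id, self.measure, self.sector)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class CohortSummary:
    """Design summary of an analyzed cohort (non-excluded sessions only)."""

    n_eyes: int
    mean_followup_years: float
    sd_followup_years: float
    median_sessions: float
    min_sessions: int
    max_sessions: int


_DEFAULT_SCHEMA = {
    "eye_id": "eye_id",
    "t_years": "t_years",
    "session_date": "session_date",
    "measure": "measure",
    "sector": "sector",
    "thickness_um": "thickness_um",
    "excluded": "excluded",
}


def read_cohort(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a long-format cohort CSV into the canonical cohort frame.

    Parameters
    ----------
    path
        CSV file with header. Time is given either as ``t_years`` (real
        years) or as ``session_date`` (ISO-8601 date, converted to years
        from each eye's first session at 365.25 days/year).
    schema
        Optional map from canonical column names (keys of the default
        schema) to the file's column names.

    Raises
    ------
    SchemaError
        if a required column is missing.
    CohortValidationError
        for non-positive thickness, unknown measure/sector tokens or
        duplicate (eye, session, measure, sector) rows.
    """
    cols = dict(_DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    raw = pd.read_csv(path)

    for req in ("eye_id", "measure", "sector", "thickness_um"):
        if cols[req] not in raw.columns:
            raise SchemaError(f"missing required column '{cols[req]}' ({req})")
    has_t = cols["t_years"] in raw.columns
    has_date = cols["session_date"] in raw.columns
    if not has_t and not has_date:
        raise SchemaError(
            f"need a time column: '{cols['t_years']}' or '{cols['session_date']}'"
        )

    df = pd.DataFrame(
        {
            "eye_id": raw[cols["eye_id"]].astype(str),
            "measure": raw[cols["measure"]].astype(str).str.strip(),
            "sector": raw[cols["sector"]].astype(str).str.strip(),
            "thickness_um": pd.to_numeric(raw[cols["thickness_um"]]),
        }
    )
    if has_t:
        df["t_years"] = pd.to_numeric(raw[cols["t_years"]])
    else:
        dates = pd.to_datetime(raw[cols["session_date"]], format="ISO8601")
        t0 = dates.groupby(df["eye_id"]).transform("min")
        df["t_years"] = (dates - t0).dt.days / DAYS_PER_YEAR
    if cols["excluded"] in raw.columns:
        df["session_excluded"] = raw[cols["excluded"]].astype(int).astype(bool)
    else:
        df["session_excluded"] = False

    bad_measure = ~df["measure"].isin(MEASURES)
    if bad_measure.any():
        row = int(np.flatnonzero(bad_measure)[0])
        raise CohortValidationError(
            f"unknown measure {df['measure'].iloc[row]!r} at data row {row}"
        )
    bad_sector = ~df["sector"].isin(SECTORS)
    if bad_sector.any():
        row = int(np.flatnonzero(bad_sector)[0])
        raise CohortValidationError(
            f"unknown sector {df['sector'].iloc[row]!r} at data row {row}"
        )
    bad_thick = ~(df["thickness_um"] > 0) | ~np.isfinite(df["thickness_um"])
    if bad_thick.any():
        row = int(np.flatnonzero(bad_thick)[0])
        raise CohortValidationError(
            f"non-positive thickness {df['thickness_um'].iloc[row]!r} at data row {row}"
        )

    df["session_index"] = _session_indices(df)
    df = _anchor_baseline(df)
    _check_duplicates(df)
    return df[COHORT_COLUMNS].reset_index(drop=True)


def _session_indices(df: pd.DataFrame) -> pd.Series:
    """Dense 0-based index of distinct session times within each eye."""
    return (
        df.groupby("eye_id")["t_years"]
        .transform(lambda s: s.rank(method="dense"))
        .astype(int)
        - 1
    )


def _anchor_baseline(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["t_years"] = df["t_years"] - df.groupby("eye_id")["t_years"].transform("min")
    return df


def _check_duplicates(df: pd.DataFrame) -> None:
    key = ["eye_id", "session_index", "measure", "sector"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise CohortValidationError(f"duplicate observation for {tuple(first)}")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a frame already in canonical layout; returns it unchanged."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing cohort columns: {missing}")
    if not (df["thickness_um"] > 0).all():
        raise CohortValidationError("non-positive thickness present")
    if not df["measure"].isin(MEASURES).all():
        raise CohortValidationError("unknown measure token present")
    if not df["sector"].isin(SECTORS).all():
        raise CohortValidationError("unknown sector token present")
    _check_duplicates(df)
    for eye, g in df.groupby("eye_id"):
        g = g.sort_values("session_index")
        if np.any(np.diff(g.groupby("session_index")["t_years"].first().values) < 0):
            raise CohortValidationError(f"eye {eye}: t_years not monotone in session")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a canonical cohort frame to CSV (round-trips with read_cohort)."""
    out = df[COHORT_COLUMNS].copy()
    out = out.rename(columns={"session_excluded": "excluded"})
    out["excluded"] = out["excluded"].astype(int)
    out.drop(columns=["session_index"]).to_csv(path, index=False)


def exclude_session(df: pd.DataFrame, eye_id: str, session_index: int) -> pd.DataFrame:
    """Flag every observation of one imaging session as excluded.

    Exclusion is session-level: both measures and all sectors of the
    session are flagged together. Idempotent.
    """
    mask = (df["eye_id"] == str(eye_id)) & (df["session_index"] == session_index)
    if not mask.any():
        raise LookupError_(f"no session {session_index} for eye {eye_id!r}")
    out = df.copy()
    out.loc[mask, "session_excluded"] = True
    return out


def summarize_cohort(df: pd.DataFrame) -> CohortSummary:
    """Summary over non-excluded sessions of the retained eyes."""
    kept = df.loc[~df["session_excluded"]]
    if kept.empty:
        raise EmptyCohortError("no non-excluded observations")
    per_eye = kept.groupby("eye_id").agg(
        n_sessions=("session_index", "nunique"),
        followup=("t_years", lambda t: t.max() - t.min()),
    )
    return CohortSummary(
        n_eyes=len(per_eye),
        mean_followup_years=float(per_eye["followup"].mean()),
        sd_followup_years=float(per_eye["followup"].std(ddof=1))
        if len(per_eye) > 1
        else 0.0,
        median_sessions=float(per_eye["n_sessions"].median()),
        min_sessions=int(per_eye["n_sessions"].min()),
        max_sessions=int(per_eye["n_sessions"].max()),
    )


def apply_eligibility(
    df: pd.DataFrame,
    min_sessions: int = 3,
    min_followup_years: float = 1.5,
) -> tuple[pd.DataFrame, CohortSummary, pd.DataFrame]:
    """Drop eyes with too few usable sessions or too little follow-up.

    Both criteria are evaluated on non-excluded sessions: at least
    ``min_sessions`` sessions and a follow-up span (last minus first
    usable session) of at least ``min_followup_years`` years.

    Returns
    -------
    (retained cohort, CohortSummary, removal report)
        The removal report has columns ``eye_id`` and ``reason``.
    """
    removals = []
    keep_eyes = []
    for eye, g in df.groupby("eye_id"):
        usable = g.loc[~g["session_excluded"]]
        n = usable["session_index"].nunique()
        span = (
            usable["t_years"].max() - usable["t_years"].min() if n > 0 else 0.0
        )
        if n < min_sessions:
            removals.append((eye, f"only {n} usable sessions (< {min_sessions})"))
        elif span < min_followup_years:
            removals.append(
                (eye, f"follow-up {span:.2f} y (< {min_followup_years} y)")
            )
        else:
            keep_eyes.append(eye)
    report = pd.DataFrame(removals, columns=["eye_id", "reason"])
    retained = df.loc[df["eye_id"].isin(keep_eyes)].reset_index(drop=True)
    if retained.empty:
        raise EmptyCohortError(
            f"no eyes meet eligibility (removed {len(removals)})"
        )
    return retained, summarize_cohort(retained), report


def to_series(df: pd.DataFrame) -> list[EyeSeries]:
    """Build per-(eye, measure, sector) series from non-excluded observations.

    Each series is sorted by time and re-anchored so its first included
    session is at t = 0. Series left with fewer than 3 points (or fewer
    than 3 distinct times) after exclusions are dropped with a warning.

    Output order is deterministic (sorted by eye, measure, sector) and
    independent of input row order.
    """
    kept = df.loc[~df["session_excluded"]]
    out: list[EyeSeries] = []
    grouped = kept.groupby(["eye_id", "measure", "sector"], sort=True)
    for (eye, measure, sector), g in grouped:
        g = g.sort_values(["t_years", "session_index"])
        t = g["t_years"].to_numpy(dtype=float)
        y = g["thickness_um"].to_numpy(dtype=float)
        if len(t) < 3 or len(np.unique(t)) < 3:
            warnings.warn(
                f"dropping series {(eye, measure, sector)}: "
                f"{len(t)} usable points",
                stacklevel=2,
            )
            continue
        out.append(EyeSeries(eye, measure, sector, t - t[0], y))
    return out
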