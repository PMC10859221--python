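"""Linearity diagnostics, export helpers and end-to-end pipeline.

The empirical-residual diagnostic centers every observation on its own
series' follow-up mean and summarizes the centered values in regular
time windows ([0,3), [3,9), [9,15), ... months). Under a truly linear
mean trend those window means trace a straight line through zero; a
systematic bend indicates nonlinearity.

``run_pipeline`` chains the full analysis — cohort I/O, eligibility,
per-eye regression, permutation classification, mixed models, LSNR,
paired comparisons and diagnostics — and writes all outputs plus a run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    EyeSeries,
    apply_eligibility,
    read_cohort,
    to_series,
    write_cohort,
)
from .compare import mcnemar_table, tabulate_proportions
from .exceptions import OctTrendError, ParameterError, PipelineStageError
from .lmm import fit_lmm_by_group, lmm_report
from .lsnr import compare_lsnr_by_sector, lsnr_table
from .permutation import cohort_permutation_table
from .simulate import DesignParams, TrajectoryParams, default_study_config, generate_cohort
from .slr import fit_all

logger = logging.getLogger("octtrend")

MONTHS_PER_YEAR = 12.0


@dataclass(frozen=True)
class WindowSummary:
    """Across-eye summary of empirical residuals in one time window."""

    window_start_months: float
    window_end_months: float
    mean_empirical_residual_um: float
    se_um: float
    n_contributing_eyes: int


def _window_index(months: np.ndarray) -> np.ndarray:
    """Window 0 is [0, 3) months; window k >= 1 is [6k - 3, 6k + 3)."""
    return np.where(months < 3.0, 0, np.floor((months + 3.0) / 6.0).astype(int))


def _window_edges(k: int) -> tuple[float, float]:
    return (0.0, 3.0) if k == 0 else (6.0 * k - 3.0, 6.0 * k + 3.0)


def empirical_residual_summary(series_list: list[EyeSeries]) -> pd.DataFrame:
    """Window means (+/- SE across eyes) of within-series centered values.

    Per observation, the empirical residual is y minus the series' mean
    over its own follow-up. Residuals are first averaged within each
    eye x window, then across eyes (so eyes with more visits in a window
    do not dominate); the SE is the between-eye standard error. Empty
    windows are omitted.
    """
    if not series_list:
        raise ParameterError("empty series collection")
    per_eye_window: dict[int, dict[tuple, float]] = {}
    for s in series_list:
        months = s.t * MONTHS_PER_YEAR
        resid = s.y - s.y.mean()
        idx = _window_index(months)
        for k in np.unique(idx):
            per_eye_window.setdefault(int(k), {})[s.key] = float(
                resid[idx == k].mean()
            )
    rows = []
    for k in sorted(per_eye_window):
        vals = np.array(list(per_eye_window[k].values()))
        lo, hi = _window_edges(k)
        rows.append(
            {
                "window_start_months": lo,
                "window_end_months": hi,
                "mean_empirical_residual_um": float(vals.mean()),
                "se_um": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else 0.0,
                "n_contributing_eyes": len(vals),
            }
        )
    return pd.DataFrame(rows)


def spaghetti_export(series_list: list[EyeSeries]) -> pd.DataFrame:
    """Lossless long-format (eye, measure, sector, t, y) export for plotting."""
    rows = []
    for s in sorted(series_list, key=lambda s: s.key):
        rows.append(
            pd.DataFrame(
                {
                    "eye_id": s.eye_id,
                    "measure": s.measure,
                    "sector": s.sector,
                    "t_years": s.t,
                    "thickness_um": s.y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _build_cohort(cfg: dict):
    if "input_csv" in cfg:
        return read_cohort(cfg["input_csv"], cfg.get("schema"))
    sim = cfg.get("simulate")
    if sim is None:
        raise ParameterError("config needs either 'input_csv' or a 'simulate' block")
    design, params = default_study_config(seed=cfg.get("seed", 0))
    if "design" in sim:
        design = DesignParams(**{**asdict(design), **sim["design"]})
    if "trajectories" in sim:
        params = {
            (m, s): TrajectoryParams(**tp)
            for (m, s), tp in (
                ((k.split("/")[0], k.split("/")[1]), v)
                for k, v in sim["trajectories"].items()
            )
        }
    cohort, _truth = generate_cohort(design, params)
    return cohort


def run_pipeline(config, out_dir) -> dict:
    """Execute the full analysis and write its report bundle.

    ``config`` is a dict or a YAML file path with keys: ``input_csv`` (+
    optional ``schema``) or ``simulate`` (optional ``design`` /
    ``trajectories`` overrides); ``seed``; ``n_perm``; ``alpha``;
    ``min_sessions``; ``min_followup_years``.

    Writes cohort.csv, slr.csv, permutation.csv, lmm.csv,
    proportions.csv, lsnr.csv, residual_windows.csv and manifest.json to
    ``out_dir``; on any stage failure, partial outputs are removed and a
    stage-tagged error is raised. Returns a dict of the written paths
    plus in-memory results.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    n_perm = int(cfg.get("n_perm", 1000))
    alpha = float(cfg.get("alpha", 0.05))

    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    stage = "cohort_io"
    try:
        cohort = _build_cohort(cfg)
        cohort, summary, removals = apply_eligibility(
            cohort,
            min_sessions=int(cfg.get("min_sessions", 3)),
            min_followup_years=float(cfg.get("min_followup_years", 1.5)),
        )
        p = out / "cohort.csv"
        write_cohort(cohort, p)
        written.append(p)
        series = to_series(cohort)
        logger.info("cohort: %d eyes, %d series", summary.n_eyes, len(series))

        stage = "slr"
        fits = fit_all(series, alpha=alpha)
        emit("slr.csv", fits)

        stage = "permutation"
        perm = cohort_permutation_table(series, n_perm=n_perm, seed=seed)
        emit("permutation.csv", perm)

        stage = "lmm"
        lmm_fits = fit_lmm_by_group(series)
        emit("lmm.csv", lmm_report(lmm_fits))

        stage = "lsnr"
        lsnr = lsnr_table(fits)
        emit("lsnr.csv", compare_lsnr_by_sector(lsnr))

        stage = "paired_compare"
        labels = fits[["eye_id", "measure", "sector", "label_slr"]].merge(
            perm[["eye_id", "measure", "sector", "label_perm"]],
            on=["eye_id", "measure", "sector"],
        )
        prop = pd.concat(
            [
                tabulate_proportions(labels, "slr_p"),
                tabulate_proportions(labels, "permutation"),
            ],
            ignore_index=True,
        )
        emit("proportions.csv", prop)
        mcn = pd.concat(
            [mcnemar_table(labels, "slr_p"), mcnemar_table(labels, "permutation")],
            ignore_index=True,
        )
        emit("mcnemar.csv", mcn)

        stage = "diagnostics"
        resid = []
        for (m, s), grp in _group_series(series).items():
            r = empirical_residual_summary(grp)
            r.insert(0, "sector", s)
            r.insert(0, "measure", m)
            resid.append(r)
        emit("residual_windows.csv", pd.concat(resid, ignore_index=True))

        stage = "manifest"
        manifest = {
            "package": "octtrend",
            "version": __version__,
            "seed": seed,
            "n_perm": n_perm,
            "alpha": alpha,
            "config_hash": _config_hash(cfg),
            "n_eyes": summary.n_eyes,
            "n_series": len(series),
            "outputs": [p.name for p in written],
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        written.append(mpath)
    except OctTrendError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc

    return {
        "out_dir": out,
        "paths": {p.name: p for p in written},
        "summary": summary,
        "removals": removals,
        "fits": fits,
        "permutation": perm,
        "lmm": lmm_fits,
        "lsnr": lsnr,
        "proportions": prop,
        "mcnemar": mcn,
        "manifest": manifest,
    }


def _group_series(series_list):
    groups: dict[tuple[str, str], list[EyeSeries]] = {}
    for s in series_list:
        groups.setdefault((s.measure, s.sector), []).append(s)
    return dict(sorted(groups.items()))
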