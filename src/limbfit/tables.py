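"""Tabular glue: fit tables, per-angle series extraction and dispersion summaries.

A *fit table* holds one record per (frame, run): the 14 fitted model
parameters in canonical order, the fitness, and convergence metadata.
From it the analysis layer builds per-angle time series (raw, run-
weighted mean, spline-interpolated, robustly smoothed) and a
Table-1-style dispersion summary: for every non-point parameter and
for the PLM angle, the mean absolute across-run difference per frame,
averaged over frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gait_analysis import (
    AngleSeries,
    interpolate_missing,
    plm_angle,
    robust_moving_average,
    run_weighted_mean,
)
from .genetic_search import FitResult
from .kinematics import PARAM_NAMES, decode, encode, wrap_angle

__all__ = [
    "FIT_TABLE_COLUMNS",
    "fit_results_to_table",
    "table_to_model",
    "angle_series_from_table",
    "analyze_fit_table",
    "dispersion_summary",
]

FIT_TABLE_COLUMNS = (
    "frame", "run", *PARAM_NAMES,
    "fitness", "generations", "evaluations", "stop_reason", "converged",
)

_ANGLE_PARAMS = ("theta1", "theta2", "theta3", "theta4")
_SUMMARY_PARAMS = ("l1", "l2", "l3", "l4", *_ANGLE_PARAMS,
                   "w1", "w2", "w3", "w4", "plm")


def fit_results_to_table(results: dict[tuple[int, int], FitResult]) -> pd.DataFrame:
    """Assemble per-(frame, run) fit results into a fit table."""
    rows = []
    for (frame, run), res in sorted(results.items()):
        rows.append([frame, run, *encode(res.model), res.fitness,
                     res.generations, res.evaluations, res.stop_reason,
                     res.converged])
    return pd.DataFrame(rows, columns=list(FIT_TABLE_COLUMNS))


def table_to_model(row: pd.Series):
    """Decode one fit-table row back into a LimbModel."""
    return decode(np.array([row[name] for name in PARAM_NAMES], dtype=float))


def _require_columns(table: pd.DataFrame, columns) -> None:
    for col in columns:
        if col not in table.columns:
            raise ValueError(f"fit table is missing required column {col!r}")


def angle_series_from_table(table: pd.DataFrame, name: str) -> tuple[list[AngleSeries], np.ndarray]:
    """Per-run AngleSeries for one angle column ('theta1'..'theta4' or 'plm').

    Returns the list of series (one per run, frame-aligned over all
    frames present in the table) and a (runs, frames) fitness array for
    weighting.  Non-converged rows are treated as missing.
    """
    _require_columns(table, ("frame", "run", "fitness", *PARAM_NAMES))
    frames = np.sort(table["frame"].unique())
    runs = np.sort(table["run"].unique())
    frame_pos = {f: i for i, f in enumerate(frames)}
    series = []
    fit = np.zeros((len(runs), len(frames)))
    for ri, run in enumerate(runs):
        sub = table[table["run"] == run]
        vals = np.full(len(frames), np.nan)
        weights = np.zeros(len(frames))
        for _, row in sub.iterrows():
            if "converged" in table.columns and not row["converged"]:
                continue
            i = frame_pos[row["frame"]]
            if name == "plm":
                vals[i] = plm_angle(table_to_model(row))
            else:
                vals[i] = wrap_angle(row[name])
            weights[i] = row["fitness"]
            fit[ri, i] = row["fitness"]
        series.append(AngleSeries(frames, vals, weights))
    return series, fit


def analyze_fit_table(
    table: pd.DataFrame, window: int = 7, outlier_k: float = 6.0
) -> dict[str, pd.DataFrame]:
    """Full per-angle analysis of a fit table.

    Returns ``{"series": ..., "summary": ...}``.  The series frame has,
    per angle (theta1..theta4 and plm), the run-weighted mean, the
    spline-interpolated mean and the robustly smoothed curve, indexed
    by frame.  The summary is the across-run dispersion table.
    """
    frames = np.sort(table["frame"].unique())
    out = pd.DataFrame({"frame": frames})
    for name in (*_ANGLE_PARAMS, "plm"):
        runs, fit = angle_series_from_table(table, name)
        mean = run_weighted_mean(runs, fit)
        out[f"{name}_mean"] = mean.values
        try:
            interp = interpolate_missing(mean)
        except ValueError:
            interp = mean
        out[f"{name}_interp"] = interp.values
        smooth = robust_moving_average(interp, window=window, outlier_k=outlier_k)
        out[f"{name}_smooth"] = smooth.values
        out[f"{name}_smooth_deg"] = np.degrees(smooth.values)
    return {"series": out, "summary": dispersion_summary(table)}


def _pairwise_mean_abs(values: np.ndarray, angular: bool) -> float:
    diffs = []
    n = values.size
    for i in range(n):
        for j in range(i + 1, n):
            d = values[i] - values[j]
            if angular:
                d = wrap_angle(d)
            diffs.append(abs(d))
    return float(np.mean(diffs))


def dispersion_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Across-run dispersion, one row per parameter plus the PLM angle.

    Per frame with at least two converged runs, the mean absolute
    pairwise difference across runs; the summary reports its mean and
    standard deviation over frames (descriptive counterpart of a
    repeated-execution variability table).
    """
    _require_columns(table, ("frame", "run", *PARAM_NAMES))
    conv = table["converged"] if "converged" in table.columns else pd.Series(
        True, index=table.index)
    rows = []
    for name in _SUMMARY_PARAMS:
        angular = name.startswith("theta") or name == "plm"
        per_frame = []
        for frame, sub in table[conv].groupby("frame"):
            if len(sub) < 2:
                continue
            if name == "plm":
                vals = np.array([plm_angle(table_to_model(r)) for _, r in sub.iterrows()])
            else:
                vals = sub[name].to_numpy(dtype=float)
                if angular:
                    vals = wrap_angle(vals)
            per_frame.append(_pairwise_mean_abs(vals, angular))
        if per_frame:
            rows.append([name, float(np.mean(per_frame)), float(np.std(per_frame)),
                         len(per_frame)])
        else:
            rows.append([name, np.nan, np.nan, 0])
    return pd.DataFrame(rows, columns=["parameter", "mean_abs_diff", "std", "n_frames"])
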