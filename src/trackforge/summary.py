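"""Per-cell summary features, MSD curves, and per-τ dataset aggregates.

Whole-track features reduce each cell to a scalar fingerprint of its
motility mode:

* ``path_length`` — total distance travelled along the track.
* ``final_displacement`` / ``max_displacement`` — net straight-line
  distance from the origin to the last point / to the farthest point.
* ``displacement_ratio`` = final / path (1 for perfectly straight
  motion, 0 for a closed loop); ``outreach_ratio`` = max / path. Both
  are confinement/straightness measures from the motility-metrics
  literature; the paper-level names are kept.
* ``arrest_coefficient`` — fraction of steps whose displacement falls
  strictly below the minimum displacement limit (ties count as motile);
  a proxy for pausing.
* ``msd_τ`` — time-averaged mean squared displacement, the mean over all
  frames t of |r(t+τΔt) − r(t)|², using overlapping windows. Ensemble
  curves average per-cell MSDs with equal cell weight so long tracks do
  not dominate.

Summary statistics (mean/median/SD) of each step metric ignore missing
values; single-point cells are reported with all motion fields missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .io_tracks import CategoryMap, TrackTable

logger = logging.getLogger(__name__)

#: step metrics that get mean/median/SD columns in the summary
_STAT_METRICS = {
    "instantaneous_displacement": "displacement",
    "instantaneous_velocity": "velocity",
    "instantaneous_acceleration": "acceleration",
    "angle_tau_1": "turn_angle",
}


def msd_curve(pos: np.ndarray, tau_max: int) -> np.ndarray:
    """Time-averaged MSD of one track for τ = 1..tau_max.

    ``msd[τ-1]`` is the mean of |r(t+τ) − r(t)|² over every valid frame
    pair (overlapping windows); NaN where the track is too short.
    """
    n = len(pos)
    out = np.full(tau_max, np.nan)
    for tau in range(1, min(tau_max, n - 1) + 1):
        d = pos[tau:] - pos[:-tau]
        out[tau - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    return out


def summarize_track(cell_steps: pd.DataFrame, pos: np.ndarray,
                    config: RunConfig) -> dict:
    """Summary-feature dict for one cell given its step records and positions."""
    n = len(cell_steps)
    t = cell_steps["t"].to_numpy()
    row: dict = {
        "cell_id": int(cell_steps["cell_id"].iloc[0]),
        "n_points": n,
        "duration": float(t[-1] - t[0]),
    }
    msd = msd_curve(pos, config.tau_max)
    if n < 2:
        for key in ("path_length", "final_displacement", "max_displacement",
                    "displacement_ratio", "outreach_ratio", "arrest_coefficient"):
            row[key] = np.nan
        for _, short in _STAT_METRICS.items():
            for stat in ("mean", "median", "sd"):
                row[f"{stat}_{short}"] = np.nan
        for tau in range(1, config.tau_max + 1):
            row[f"msd_{tau}"] = np.nan
        return row

    disp = cell_steps["instantaneous_displacement"].to_numpy()
    total = cell_steps["total_displacement"].to_numpy()
    path_length = float(np.nansum(disp))
    final_disp = float(total[-1])
    max_disp = float(np.nanmax(total))
    steps = disp[~np.isnan(disp)]
    row.update(
        path_length=path_length,
        final_displacement=final_disp,
        max_displacement=max_disp,
        displacement_ratio=final_disp / path_length if path_length > 0 else np.nan,
        outreach_ratio=max_disp / path_length if path_length > 0 else np.nan,
        arrest_coefficient=float(np.mean(steps < config.min_displacement)),
    )
    for col, short in _STAT_METRICS.items():
        vals = cell_steps[col].dropna() if col in cell_steps else pd.Series(dtype=float)
        row[f"mean_{short}"] = float(vals.mean()) if len(vals) else np.nan
        row[f"median_{short}"] = float(vals.median()) if len(vals) else np.nan
        row[f"sd_{short}"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    for tau in range(1, config.tau_max + 1):
        row[f"msd_{tau}"] = msd[tau - 1]
    return row


def summarize_tracks(table: TrackTable, steps: pd.DataFrame,
                     config: RunConfig) -> pd.DataFrame:
    """One summary row per cell (see module docstring for field definitions)."""
    rows = []
    for cid, cell_steps in steps.groupby("cell_id", sort=True):
        pos = table.df.loc[table.df["cell_id"] == cid, ["x", "y", "z"]].to_numpy(dtype=float)
        rows.append(summarize_track(cell_steps, pos, config))
    return pd.DataFrame(rows)


def msd_table(summaries: pd.DataFrame, tau_max: int) -> pd.DataFrame:
    """Per-cell MSD curves as a cells × τ sheet."""
    cols = ["cell_id"] + [f"msd_{tau}" for tau in range(1, tau_max + 1)]
    return summaries[[c for c in cols if c in summaries.columns]].copy()


def aggregate_tau(steps: pd.DataFrame, categories: CategoryMap | None = None,
                  tau_max: int | None = None) -> pd.DataFrame:
    """Mean/SD of the τ-lagged Euclidean distance, overall and per category.

    Pools every valid (cell, timepoint) observation of ``euclid_tau_τ``.
    One ``overall`` row per τ, plus one row per category when a category
    map is supplied; categories with no valid observations at a τ are
    omitted with a warning.
    """
    tau_cols = sorted(
        (c for c in steps.columns if c.startswith("euclid_tau_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if tau_max is not None:
        tau_cols = tau_cols[:tau_max]

    def _rows(sub: pd.DataFrame, scope: str):
        for col in tau_cols:
            vals = sub[col].dropna()
            if vals.empty:
                logger.warning("no %s observations for scope %r; row omitted", col, scope)
                continue
            yield {
                "scope": scope,
                "tau": int(col.rsplit("_", 1)[1]),
                "mean_euclid": float(vals.mean()),
                "sd_euclid": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            }

    rows = list(_rows(steps, "overall"))
    if categories is not None and len(categories):
        labels = steps["cell_id"].map(lambda c: categories.get(int(c)))
        for cat in sorted(set(categories.mapping.values())):
            sub = steps[labels == cat]
            if sub.empty:
                logger.warning("category %r has no tracked steps; rows omitted", cat)
                continue
            rows.extend(_rows(sub, cat))
    return pd.DataFrame(rows, columns=["scope", "tau", "mean_euclid", "sd_euclid", "n"])
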