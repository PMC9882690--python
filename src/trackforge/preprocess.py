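"""Track repair: multiplet averaging, gap interpolation, 3D→2D flattening.

Real segmentation/tracking output often carries two defects that break
downstream per-frame arithmetic: several coordinates for one cell at one
timepoint (over-segmentation) and missing timepoints (dropped
detections). Averaging resolves the former into a single centroid; linear
interpolation fills the latter on the regular frame grid. Both leave the
original file untouched and mark every repaired point with a provenance
flag so users can audit or exclude heavily repaired tracks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_tracks import FLAG_AVERAGED, FLAG_INTERPOLATED, TrackTable

logger = logging.getLogger(__name__)

#: Relative tolerance for deciding a timestamp sits on the frame grid.
GRID_RTOL = 1e-6


def average_multiplets(table: TrackTable) -> TrackTable:
    """Collapse duplicate (cell, time) observations into their mean position.

    Each multiplet becomes one point at the arithmetic mean of its
    coordinates, flagged ``averaged``. Tables without duplicates are
    returned unchanged (idempotent).
    """
    df = table.df
    dup_mask = df.duplicated(["cell_id", "t"], keep=False)
    if not dup_mask.any():
        return table
    singles = df[~dup_mask]
    merged = (
        df[dup_mask]
        .groupby(["cell_id", "t"], as_index=False)[["x", "y", "z"]]
        .mean()
        .assign(flag=FLAG_AVERAGED)
    )
    logger.info("averaged %d multiplet groups", len(merged))
    out = pd.concat([singles, merged], ignore_index=True)
    return table.with_df(out)


def infer_frame_interval(table: TrackTable) -> float:
    """Median of all positive within-cell consecutive time differences."""
    diffs = table.df.groupby("cell_id")["t"].diff().dropna()
    diffs = diffs[diffs > 0]
    if diffs.empty:
        raise ValidationError(
            "cannot infer frame interval: no cell has two distinct timepoints"
        )
    return float(diffs.median())


def _grid_index(t: np.ndarray, t0: float, dt: float) -> np.ndarray:
    k = np.round((t - t0) / dt)
    expected = t0 + k * dt
    scale = np.maximum(np.abs(t), dt)
    if np.any(np.abs(t - expected) > GRID_RTOL * scale):
        off = t[np.abs(t - expected) > GRID_RTOL * scale][0]
        raise ValidationError(
            f"timepoint t={off} does not sit on the frame grid "
            f"(interval {dt}); resample the data to a regular interval"
        )
    return k.astype(np.int64)


def interpolate_gaps(table: TrackTable, frame_interval: float | None = None) -> TrackTable:
    """Fill missing internal frames of each track by linear interpolation.

    For each cell, every multiple of the frame interval strictly between
    its first and last observation that has no point is filled by
    per-coordinate linear interpolation between the nearest observed
    neighbours; filled points are flagged ``interpolated``. Nothing is
    extrapolated beyond a track's ends. Multiplets must be averaged first
    (duplicate timepoints make gap detection ambiguous).
    """
    if table.df.duplicated(["cell_id", "t"]).any():
        raise ValidationError("average multiplets before interpolating gaps")
    dt = infer_frame_interval(table) if frame_interval is None else float(frame_interval)
    if dt <= 0:
        raise ValidationError("frame_interval must be positive")
    t0 = float(table.df["t"].min())  # global grid origin keeps cells frame-aligned

    pieces = []
    n_filled = 0
    for cid, g in table.df.groupby("cell_id", sort=True):
        t = g["t"].to_numpy(dtype=float)
        k = _grid_index(t, t0, dt)
        full_k = np.arange(k[0], k[-1] + 1)
        if len(full_k) == len(k):
            pieces.append(g)
            continue
        full_t = t0 + full_k * dt
        cols = {"cell_id": cid, "t": full_t}
        for c in ("x", "y", "z"):
            cols[c] = np.interp(full_k, k, g[c].to_numpy(dtype=float))
        filled = pd.DataFrame(cols)
        flags = np.full(len(full_k), FLAG_INTERPOLATED, dtype=object)
        flags[np.isin(full_k, k)] = g["flag"].to_numpy()
        filled["flag"] = flags
        gap_frac = 1 - len(k) / len(full_k)
        logger.info("cell %s: interpolated %d of %d frames (%.1f%%)",
                    cid, len(full_k) - len(k), len(full_k), 100 * gap_frac)
        n_filled += len(full_k) - len(k)
        pieces.append(filled)
    if n_filled == 0:
        return table.with_df(table.df, frame_interval=dt)
    return table.with_df(pd.concat(pieces, ignore_index=True), frame_interval=dt)


def flatten_to_2d(table: TrackTable) -> TrackTable:
    """Drop the axial dimension: set z = 0 everywhere and mark the table 2D."""
    if table.is_2d and (table.df["z"] == 0).all():
        return table
    df = table.df.copy()
    df["z"] = 0.0
    return table.with_df(df, is_2d=True)


def preprocess(table: TrackTable, *, interpolate: bool = True,
               flatten: bool = False) -> TrackTable:
    """Full repair pipeline: average → (flatten) → (interpolate).

    Returns a regular-interval table with ``frame_interval`` set.
    """
    out = average_multiplets(table)
    if flatten:
        out = flatten_to_2d(out)
    dt = infer_frame_interval(out)
    if interpolate:
        out = interpolate_gaps(out, dt)
    else:
        out = out.with_df(out.df, frame_interval=dt)
    return out
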