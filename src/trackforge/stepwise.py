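"""Per-timepoint (step-based) motility metrics.

For every cell and frame: instantaneous displacement, running path
length, net displacement from the track origin, instantaneous velocity
and acceleration, and τ-lagged Euclidean distances and relative turning
angles for τ = 1..tau_max. Lagged quantities use overlapping windows
(every frame where both endpoints exist), the standard practice for
time-averaged MSD-type statistics.

Turning angles are unsigned, in degrees on [0, 180]: 3D trajectories
have no canonical sign convention, so the angle between successive
τ-lagged displacement vectors is reported. A per-timepoint minimum
displacement limit filters the angles: if either leg of the angle moved
less than ``min_displacement * tau`` in total, the angle is treated as
sub-resolution jitter and omitted. Leading undefined values (first frame
has no displacement, first two no acceleration) are emitted as missing,
never as zeros, so they cannot bias summary statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .io_tracks import TrackTable

logger = logging.getLogger(__name__)


def turning_angle(p_prev, p_mid, p_next, min_displacement: float, tau: int = 1) -> float:
    """Unsigned relative turning angle at ``p_mid``, in degrees.

    ``p_prev``/``p_next`` are the positions τ frames before/after
    ``p_mid``. Returns the angle between the incoming and outgoing
    displacement vectors, or NaN when either leg is shorter than
    ``min_displacement * tau`` (including exactly-zero legs when the
    limit is 0, which would make the angle undefined).
    """
    v1 = np.asarray(p_mid, dtype=float) - np.asarray(p_prev, dtype=float)
    v2 = np.asarray(p_next, dtype=float) - np.asarray(p_mid, dtype=float)
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    threshold = min_displacement * tau
    if n1 < threshold or n2 < threshold or n1 == 0.0 or n2 == 0.0:
        return float("nan")
    # atan2(|v1 x v2|, v1.v2) is numerically exact near 0 and 180 degrees,
    # where the arccos form loses ~1e-6 deg to rounding
    cross = np.linalg.norm(np.cross(v1, v2))
    return float(np.degrees(np.arctan2(cross, np.dot(v1, v2))))


def _cell_steps(cid: int, g: pd.DataFrame, dt: float, tau_max: int,
                min_displacement: float) -> pd.DataFrame:
    pos = g[["x", "y", "z"]].to_numpy(dtype=float)
    t = g["t"].to_numpy(dtype=float)
    n = len(g)

    disp = np.full(n, np.nan)
    if n > 1:
        disp[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path = np.nancumsum(disp)
    total = np.linalg.norm(pos - pos[0], axis=1)
    vel = disp / dt
    acc = np.full(n, np.nan)
    if n > 2:
        acc[2:] = np.diff(vel[1:]) / dt

    out = pd.DataFrame(
        {
            "cell_id": cid,
            "t": t,
            "instantaneous_displacement": disp,
            "path_length_cum": path,
            "total_displacement": total,
            "instantaneous_velocity": vel,
            "instantaneous_acceleration": acc,
        }
    )
    for tau in range(1, tau_max + 1):
        eu = np.full(n, np.nan)
        ang = np.full(n, np.nan)
        if tau < n:
            eu[tau:] = np.linalg.norm(pos[tau:] - pos[:-tau], axis=1)
        if 2 * tau < n:
            v1 = pos[tau:-tau] - pos[: -2 * tau]
            v2 = pos[2 * tau:] - pos[tau:-tau]
            n1 = np.linalg.norm(v1, axis=1)
            n2 = np.linalg.norm(v2, axis=1)
            thr = min_displacement * tau
            ok = (n1 >= thr) & (n2 >= thr) & (n1 > 0) & (n2 > 0)
            cross = np.linalg.norm(np.cross(v1, v2), axis=1)
            vals = np.degrees(np.arctan2(cross, np.einsum("ij,ij->i", v1, v2)))
            vals[~ok] = np.nan
            ang[tau:-tau] = vals
        out[f"euclid_tau_{tau}"] = eu
        out[f"angle_tau_{tau}"] = ang
    return out


def compute_steps(table: TrackTable, config: RunConfig) -> pd.DataFrame:
    """One row of step metrics per (cell, timepoint).

    The table must be preprocessed to a regular frame interval. Lags
    exceeding a track's length are simply absent for that cell (a
    warning is logged if no track supports ``tau_max``).
    """
    dt = table.frame_interval
    if dt is None or dt <= 0:
        raise ValueError("table.frame_interval must be set; run preprocess first")
    pieces = [
        _cell_steps(cid, g, dt, config.tau_max, config.min_displacement)
        for cid, g in table.df.groupby("cell_id", sort=True)
    ]
    steps = pd.concat(pieces, ignore_index=True)
    longest = int(table.df.groupby("cell_id").size().max())
    if config.tau_max >= longest:
        logger.warning(
            "tau_max=%d is not shorter than the longest track (%d points); "
            "longer lags are absent", config.tau_max, longest,
        )
    return steps
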