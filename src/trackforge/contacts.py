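"""Cell-cell contact detection, division/dead-cell filtering, summaries.

Two cells are in contact at a timepoint when their centroid distance is
strictly below the user's contact limit; maximal consecutive runs of
in-contact frames become contact events. Two filters remove artifacts:

* Division filter — cell pairs whose integer IDs differ by exactly one
  are treated as daughter cells (trackers typically assign adjacent IDs
  at a split) and all their contacts are removed: post-cytokinesis
  proximity is not a newly formed cell-cell contact.
* Dead-cell filter — contacts touching any cell whose arrest
  coefficient is strictly above the arrest limit are removed, since a
  non-motile (possibly dead) cell sitting next to a mover is not a
  biologically meaningful interaction.

Both thresholds are strict inequalities; ties fall on the keep /
no-contact side. Detection is run before filtering so both the raw and
filtered event tables can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_tracks import FLAG_ORIGINAL, TrackTable

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "cell_a", "cell_b", "t_start", "t_end", "duration", "n_frames", "any_interpolated",
]


@dataclass(frozen=True)
class ContactEvent:
    """A maximal run of frames during which one cell pair stays in contact."""

    cell_a: int
    cell_b: int
    t_start: float
    t_end: float
    duration: float
    n_frames: int
    any_interpolated: bool = False


def events_to_frame(events: list[ContactEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events], columns=EVENT_COLUMNS)


def detect_contacts(table: TrackTable, contact_limit: float,
                    frame_interval: float | None = None) -> list[ContactEvent]:
    """Find all maximal contact events at the given distance limit.

    Every unordered pair of distinct cells co-tracked at a frame is in
    contact there iff their Euclidean distance < ``contact_limit``. A
    single-frame contact has duration one frame interval (an event's
    duration is ``t_end - t_start + frame_interval``). Events spanning
    any interpolated position are flagged. All-pairs/all-frames is
    O(cells² × frames) — exact by construction, and fast enough for
    typical timelapse datasets (hundreds of cells).
    """
    dt = frame_interval if frame_interval is not None else table.frame_interval
    if dt is None or dt <= 0:
        raise ValueError("frame_interval must be known; run preprocess first")

    df = table.df
    # (pair -> sorted list of (frame index, interpolated flag)) of in-contact frames
    t0 = float(df["t"].min())
    in_contact: dict[tuple[int, int], list[tuple[int, bool]]] = {}
    for t, g in df.groupby("t", sort=True):
        if len(g) < 2:
            continue
        frame = int(round((t - t0) / dt))
        ids = g["cell_id"].to_numpy()
        interp = (g["flag"].to_numpy() != FLAG_ORIGINAL)
        dists = squareform(pdist(g[["x", "y", "z"]].to_numpy(dtype=float)))
        ii, jj = np.nonzero(np.triu(dists < contact_limit, k=1))
        for i, j in zip(ii, jj):
            a, b = int(ids[i]), int(ids[j])
            if a == b:
                continue  # duplicate rows of one cell are not a self-contact
            pair = (min(a, b), max(a, b))
            in_contact.setdefault(pair, []).append((frame, bool(interp[i] or interp[j])))

    events: list[ContactEvent] = []
    for (a, b), hits in sorted(in_contact.items()):
        hits.sort()
        run_start = prev = hits[0][0]
        run_interp = hits[0][1]
        for frame, flag in hits[1:]:
            if frame == prev + 1:
                run_interp = run_interp or flag
            else:
                events.append(_make_event(a, b, run_start, prev, t0, dt, run_interp))
                run_start, run_interp = frame, flag
            prev = frame
        events.append(_make_event(a, b, run_start, prev, t0, dt, run_interp))
    logger.info("detected %d contact events among %d pairs", len(events), len(in_contact))
    return events


def _make_event(a: int, b: int, f_start: int, f_end: int, t0: float, dt: float,
                any_interp: bool) -> ContactEvent:
    t_start = t0 + f_start * dt
    t_end = t0 + f_end * dt
    return ContactEvent(
        cell_a=a, cell_b=b, t_start=t_start, t_end=t_end,
        duration=t_end - t_start + dt, n_frames=f_end - f_start + 1,
        any_interpolated=any_interp,
    )


def filter_divisions(events: list[ContactEvent]) -> list[ContactEvent]:
    """Drop every event between ID-adjacent cells (|cell_a − cell_b| = 1)."""
    kept = [e for e in events if abs(e.cell_a - e.cell_b) != 1]
    if len(kept) < len(events):
        logger.info("division filter removed %d events", len(events) - len(kept))
    return kept


def filter_dead(events: list[ContactEvent], summaries: pd.DataFrame,
                arrest_limit: float) -> list[ContactEvent]:
    """Drop events touching a non-motile cell (arrest coefficient > limit).

    ``summaries`` must have been computed with the same minimum
    displacement limit. Events referencing a cell with no usable arrest
    coefficient (e.g. a single-point track) are removed with a warning.
    """
    arrest = summaries.set_index("cell_id")["arrest_coefficient"]
    kept = []
    for e in events:
        vals = [arrest.get(e.cell_a), arrest.get(e.cell_b)]
        if any(v is None or np.isnan(v) for v in vals):
            logger.warning(
                "contact (%d, %d) references a cell without an arrest "
                "coefficient; event removed", e.cell_a, e.cell_b,
            )
            continue
        if any(v > arrest_limit for v in vals):
            continue
        kept.append(e)
    if len(kept) < len(events):
        logger.info("dead-cell filter removed %d events", len(events) - len(kept))
    return kept


def summarize_contacts(events: list[ContactEvent], table: TrackTable) -> pd.DataFrame:
    """Per-cell contact history: count, total time in contact, median duration.

    Every cell in the table gets a row; cells with no contacts get zero
    count/time and a missing median.
    """
    per_cell: dict[int, list[float]] = {int(c): [] for c in table.cell_ids}
    for e in events:
        per_cell.setdefault(e.cell_a, []).append(e.duration)
        per_cell.setdefault(e.cell_b, []).append(e.duration)
    rows = [
        {
            "cell_id": cid,
            "n_contacts": len(durs),
            "total_contact_time": float(np.sum(durs)) if durs else 0.0,
            "median_contact_duration": float(np.median(durs)) if durs else np.nan,
        }
        for cid, durs in sorted(per_cell.items())
    ]
    return pd.DataFrame(rows)
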