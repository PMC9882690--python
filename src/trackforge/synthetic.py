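"""Synthetic track generators with known ground truth.

These emulate regular-interval 2D/3D timelapse centroid tracks under
three canonical motion models — ballistic (constant speed, fixed random
direction), Brownian (i.i.d. Gaussian steps; ensemble MSD(τ) =
dims·step_sd²·τ), and arrested (Gaussian jitter about a fixed point) —
plus a persistent random walk that sits between ballistic and Brownian.
Scenario generation adds the defects and events the pipeline must
handle: deleted frames, duplicated frames, ID-adjacent division pairs,
and scripted approach/contact/retreat cell pairs with known contact
frames. All generators are deterministic given a seed and emit valid
track tables in the same dialect the readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .io_tracks import FLAG_ORIGINAL, CategoryMap, TrackTable


def _table(frames: list[pd.DataFrame], frame_interval: float,
           dims: int) -> TrackTable:
    df = pd.concat(frames, ignore_index=True)
    df["flag"] = FLAG_ORIGINAL
    return TrackTable(df, is_2d=(dims == 2), frame_interval=frame_interval)


def _cell_frame(cell_id: int, pos: np.ndarray, frame_interval: float,
                t0: float = 0.0) -> pd.DataFrame:
    n = len(pos)
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "t": t0 + frame_interval * np.arange(n),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2] if pos.shape[1] == 3 else 0.0,
        }
    )


def _unit_directions(rng: np.random.Generator, n: int, dims: int) -> np.ndarray:
    v = rng.normal(size=(n, dims))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _pad3(pos: np.ndarray) -> np.ndarray:
    if pos.shape[1] == 3:
        return pos
    return np.hstack([pos, np.zeros((len(pos), 1))])


def make_ballistic(n_cells: int, n_steps: int, speed: float = 2.0,
                   frame_interval: float = 1.0, dims: int = 3,
                   seed: int = 0, start_spread: float = 0.0) -> TrackTable:
    """Constant-speed straight-line movers with random fixed directions."""
    rng = np.random.default_rng(seed)
    dirs = _unit_directions(rng, n_cells, dims)
    starts = rng.uniform(-start_spread, start_spread, size=(n_cells, dims))
    frames = []
    for i in range(n_cells):
        steps = np.tile(dirs[i] * speed * frame_interval, (n_steps, 1))
        pos = starts[i] + np.vstack([np.zeros(dims), np.cumsum(steps, axis=0)])
        frames.append(_cell_frame(i + 1, _pad3(pos), frame_interval))
    return _table(frames, frame_interval, dims)


def make_brownian(n_cells: int, n_steps: int, step_sd: float = 1.0,
                  dims: int = 3, frame_interval: float = 1.0,
                  seed: int = 0, start_spread: float = 0.0) -> TrackTable:
    """Unbiased random walks: i.i.d. Gaussian increments per coordinate."""
    if step_sd <= 0:
        raise ValidationError("step_sd must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_cells):
        start = rng.uniform(-start_spread, start_spread, size=dims)
        incr = rng.normal(scale=step_sd, size=(n_steps, dims))
        pos = start + np.vstack([np.zeros(dims), np.cumsum(incr, axis=0)])
        frames.append(_cell_frame(i + 1, _pad3(pos), frame_interval))
    return _table(frames, frame_interval, dims)


def make_arrested(n_cells: int, n_steps: int, jitter_sd: float = 0.01,
                  dims: int = 3, frame_interval: float = 1.0,
                  seed: int = 0, start_spread: float = 50.0) -> TrackTable:
    """Non-motile cells jittering about fixed anchor points."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_cells):
        anchor = rng.uniform(-start_spread, start_spread, size=dims)
        pos = anchor + rng.normal(scale=jitter_sd, size=(n_steps + 1, dims))
        frames.append(_cell_frame(i + 1, _pad3(pos), frame_interval))
    return _table(frames, frame_interval, dims)


def make_persistent(n_cells: int, n_steps: int, speed: float = 2.0,
                    turn_sd_deg: float = 20.0, dims: int = 3,
                    frame_interval: float = 1.0, seed: int = 0,
                    start_spread: float = 0.0) -> TrackTable:
    """Persistent random walk: each step rotates the heading by a small
    random angle, interpolating between ballistic and Brownian motion."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_cells):
        heading = _unit_directions(rng, 1, dims)[0]
        start = rng.uniform(-start_spread, start_spread, size=dims)
        pos = [start]
        for _ in range(n_steps):
            # perturb heading with Gaussian angular noise, renormalize
            noise = rng.normal(scale=np.radians(turn_sd_deg), size=dims)
            heading = heading + noise
            heading = heading / np.linalg.norm(heading)
            pos.append(pos[-1] + heading * speed * frame_interval)
        frames.append(_cell_frame(i + 1, _pad3(np.asarray(pos)), frame_interval))
    return _table(frames, frame_interval, dims)


# ---------------------------------------------------------------------------
# scripted scenarios

@dataclass
class CellSpec:
    """One scripted cell: motion model, optional defects, optional label."""

    cell_id: int
    model: str = "ballistic"            # ballistic | brownian | arrested
    speed: float = 2.0
    step_sd: float = 1.0
    jitter_sd: float = 0.01
    start: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] | None = None
    category: str | None = None
    delete_frames: list[int] = field(default_factory=list)
    duplicate_frames: list[int] = field(default_factory=list)


@dataclass
class ContactPairSpec:
    """Two cells scripted to be within ``separation`` of each other for
    frames ``start``..``end`` inclusive, and far apart otherwise."""

    cell_a: int
    cell_b: int
    start: int
    end: int
    separation: float = 2.0
    far: float = 100.0
    base: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class Scenario:
    cells: list[CellSpec] = field(default_factory=list)
    contact_pairs: list[ContactPairSpec] = field(default_factory=list)
    n_steps: int = 20
    frame_interval: float = 1.0


@dataclass
class GroundTruth:
    """What the generated data is known to contain."""

    contact_events: list[tuple[int, int, int, int]]  # (a, b, frame_start, frame_end)
    deleted_points: pd.DataFrame                     # true coordinates of removed frames
    categories: CategoryMap


def _cell_positions(spec: CellSpec, n_points: int, dt: float,
                    rng: np.random.Generator) -> np.ndarray:
    start = np.asarray(spec.start, dtype=float)
    if spec.model == "ballistic":
        d = (np.asarray(spec.direction, dtype=float)
             if spec.direction is not None else _unit_directions(rng, 1, 3)[0])
        d = d / np.linalg.norm(d)
        return start + np.outer(np.arange(n_points), d * spec.speed * dt)
    if spec.model == "brownian":
        incr = rng.normal(scale=spec.step_sd, size=(n_points - 1, 3))
        return start + np.vstack([np.zeros(3), np.cumsum(incr, axis=0)])
    if spec.model == "arrested":
        return start + rng.normal(scale=spec.jitter_sd, size=(n_points, 3))
    raise ValidationError(f"unknown motion model {spec.model!r}")


def make_scenario(scenario: Scenario, seed: int = 0) -> tuple[TrackTable, GroundTruth]:
    """Generate a scripted dataset plus its ground-truth record.

    Scripted contact pairs override motion: cell_a moves ballistically
    from ``base``; cell_b shadows it at ``separation`` during the
    contact window and at ``far`` outside it, so the true contact frames
    are known exactly. Deleted frames (interior only) are recorded with
    their true coordinates for interpolation-recovery assertions;
    duplicated frames get a second, identical row.
    """
    rng = np.random.default_rng(seed)
    n_points = scenario.n_steps + 1
    dt = scenario.frame_interval
    all_ids = [c.cell_id for c in scenario.cells] + [
        i for p in scenario.contact_pairs for i in (p.cell_a, p.cell_b)
    ]
    if len(set(all_ids)) != len(all_ids):
        raise ValidationError("scenario assigns the same cell_id twice")

    frames: list[pd.DataFrame] = []
    deleted_rows = []
    true_contacts = []
    categories: dict[int, str] = {}

    for spec in scenario.cells:
        if spec.category is not None:
            categories[spec.cell_id] = spec.category
        dels = sorted(set(spec.delete_frames))
        if len(dels) != len(spec.delete_frames):
            raise ValidationError(
                f"cell {spec.cell_id}: a frame is listed for deletion twice"
            )
        if any(f <= 0 or f >= n_points - 1 for f in dels):
            raise ValidationError(
                f"cell {spec.cell_id}: only interior frames can be deleted"
            )
        pos = _cell_positions(spec, n_points, dt, rng)
        frame = _cell_frame(spec.cell_id, pos, dt)
        for f in dels:
            deleted_rows.append(
                {"cell_id": spec.cell_id, "t": f * dt,
                 "x": pos[f, 0], "y": pos[f, 1], "z": pos[f, 2]}
            )
        keep = frame.drop(index=dels)
        dup = frame.loc[[f for f in spec.duplicate_frames if f not in dels]]
        frames.append(pd.concat([keep, dup], ignore_index=True))

    for pair in scenario.contact_pairs:
        if not 0 <= pair.start <= pair.end <= n_points - 1:
            raise ValidationError("contact window must lie within the track")
        base = np.asarray(pair.base, dtype=float)
        d = _unit_directions(rng, 1, 3)[0]
        pos_a = base + np.outer(np.arange(n_points), d * 2.0 * dt)
        offset = np.full(n_points, pair.far)
        offset[pair.start:pair.end + 1] = pair.separation
        # offset along a fixed axis orthogonal-ish to the heading
        perp = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.array([1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        pos_b = pos_a + offset[:, None] * perp
        frames.append(_cell_frame(pair.cell_a, pos_a, dt))
        frames.append(_cell_frame(pair.cell_b, pos_b, dt))
        a, b = sorted((pair.cell_a, pair.cell_b))
        true_contacts.append((a, b, pair.start, pair.end))

    table = _table(frames, dt, dims=3)
    truth = GroundTruth(
        contact_events=sorted(true_contacts),
        deleted_points=pd.DataFrame(
            deleted_rows, columns=["cell_id", "t", "x", "y", "z"]
        ),
        categories=CategoryMap(categories),
    )
    return table, truth


def load_scenario(path) -> Scenario:
    """Read a scenario from a human-readable YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cells = [CellSpec(**{**c, "start": tuple(c.get("start", (0, 0, 0)))})
             for c in raw.get("cells", [])]
    pairs = [ContactPairSpec(**{**p, "base": tuple(p.get("base", (0, 0, 0)))})
             for p in raw.get("contact_pairs", [])]
    return Scenario(
        cells=cells,
        contact_pairs=pairs,
        n_steps=int(raw.get("n_steps", 20)),
        frame_interval=float(raw.get("frame_interval", 1.0)),
    )
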