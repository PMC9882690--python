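"""Reading/validating track and category CSVs and writing result workbooks.

Input files are never modified; all outputs go to new XLSX workbooks (or
CSV exports of the same sheets). A tracks CSV needs one row per cell per
timepoint with an integer cell identifier, the time, and X/Y(/Z)
coordinates; header names are configurable and matched case-insensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_COLUMNS
from .exceptions import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical column order of a TrackTable frame.
TRACK_COLUMNS = ["cell_id", "t", "x", "y", "z", "flag"]

#: Provenance flags.
FLAG_ORIGINAL = "original"
FLAG_INTERPOLATED = "interpolated"
FLAG_AVERAGED = "averaged"

#: Fixed sheet order of the main results workbook.
MAIN_SHEETS = [
    "Formatted_Data",
    "Step_Metrics",
    "Summary_Statistics",
    "MSD",
    "Tau_Aggregates",
    "Contacts",
    "Contact_Summary",
]

#: Fixed sheet order of the PCA workbook.
PCA_SHEETS = ["Loadings", "Explained_Variance", "Scores", "KW_Tests", "Dunn_Pairwise"]


@dataclass
class TrackTable:
    """A validated, time-sorted collection of track points.

    ``df`` holds one row per observation with columns
    ``cell_id, t, x, y, z, flag`` sorted by ``(cell_id, t)``.
    ``is_2d`` marks data without a meaningful Z coordinate and
    ``frame_interval`` the common time step once known.
    """

    df: pd.DataFrame
    is_2d: bool = False
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"TrackTable frame lacks columns {missing}")
        df = df[TRACK_COLUMNS].sort_values(["cell_id", "t"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].unique()

    @property
    def n_cells(self) -> int:
        return self.df["cell_id"].nunique()

    def positions(self, cell_id: int) -> np.ndarray:
        """(n, 3) coordinate array of one cell, time-ordered."""
        g = self.df[self.df["cell_id"] == cell_id]
        return g[["x", "y", "z"]].to_numpy(dtype=float)

    def with_df(self, df: pd.DataFrame, **kwargs) -> "TrackTable":
        """Copy of this table with a replacement frame (re-validated)."""
        out = replace(self, df=df)
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out

    def to_csv(self, path: str | Path, column_names: dict[str, str] | None = None) -> None:
        """Write the table in the same CSV dialect ``read_tracks`` consumes."""
        cols = dict(DEFAULT_COLUMNS if column_names is None else column_names)
        out = self.df[["cell_id", "t", "x", "y", "z"]].rename(
            columns={k: cols.get(k, k) for k in ("cell_id", "t", "x", "y", "z")}
        )
        out.to_csv(path, index=False)


@dataclass
class CategoryMap:
    """Mapping cell_id -> category label (verbatim strings)."""

    mapping: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, cell_id: int) -> str:
        return self.mapping[int(cell_id)]

    def get(self, cell_id: int, default=None):
        return self.mapping.get(int(cell_id), default)

    def labels_for(self, cell_ids) -> pd.Series:
        return pd.Series([self.mapping.get(int(c)) for c in cell_ids], index=cell_ids)

    def validate_against(self, table: TrackTable) -> None:
        """Every mapped cell must exist in the table (unmapped cells are fine)."""
        known = set(int(c) for c in table.cell_ids)
        orphans = sorted(c for c in self.mapping if c not in known)
        if orphans:
            raise ValidationError(
                f"categories reference cell IDs absent from the tracks: {orphans[:10]}"
            )


def _resolve_columns(header: list[str], column_names: dict[str, str]) -> dict[str, str | None]:
    """Map canonical names to actual CSV headers, case-insensitively."""
    lower = {h.strip().lower(): h for h in header}
    resolved: dict[str, str | None] = {}
    for canonical in ("cell_id", "t", "x", "y", "z"):
        wanted = column_names.get(canonical)
        if wanted is None:
            resolved[canonical] = None
            continue
        actual = lower.get(wanted.strip().lower())
        if actual is None and canonical == "z":
            resolved[canonical] = None  # Z is optional: 2D data
            continue
        if actual is None:
            raise FormatError(
                f"tracks file is missing the {canonical!r} column "
                f"(expected header {wanted!r}; found {header})"
            )
        resolved[canonical] = actual
    return resolved


def _numeric(series: pd.Series, name: str) -> pd.Series:
    values = pd.to_numeric(series, errors="coerce")
    bad = values.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"non-numeric value {series[bad.idxmax()]!r} in column {name!r}", row=row)
    if values.isna().any():
        row = int(values.isna().idxmax()) + 2
        raise ParseError(f"empty value in column {name!r}", row=row)
    return values.astype(float)


def read_tracks(path: str | Path, column_names: dict[str, str] | None = None) -> TrackTable:
    """Read a tracks CSV into a validated :class:`TrackTable`.

    Each row is one cell at one timepoint. A missing Z column yields
    ``z = 0`` everywhere and marks the table 2D. Duplicate ``(cell_id, t)``
    rows are retained (to be averaged during preprocessing). Cell IDs must
    be integers because the division filter compares IDs arithmetically.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"tracks file not found: {path}")
    cols = dict(DEFAULT_COLUMNS)
    cols.update(column_names or {})
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    resolved = _resolve_columns(list(raw.columns), cols)

    ids_raw = _numeric(raw[resolved["cell_id"]], resolved["cell_id"])
    if not np.all(ids_raw == np.round(ids_raw)):
        bad = int((ids_raw != np.round(ids_raw)).idxmax()) + 2
        raise ParseError(
            "cell IDs must be integers (the division filter compares IDs arithmetically)",
            row=bad,
        )
    df = pd.DataFrame(
        {
            "cell_id": ids_raw.astype(np.int64),
            "t": _numeric(raw[resolved["t"]], resolved["t"]),
            "x": _numeric(raw[resolved["x"]], resolved["x"]),
            "y": _numeric(raw[resolved["y"]], resolved["y"]),
        }
    )
    is_2d = resolved["z"] is None
    df["z"] = 0.0 if is_2d else _numeric(raw[resolved["z"]], resolved["z"])
    df["flag"] = FLAG_ORIGINAL
    table = TrackTable(df, is_2d=is_2d)
    n_dup = int(table.df.duplicated(["cell_id", "t"]).sum())
    if n_dup:
        logger.warning("%d duplicated (cell, time) rows retained for averaging", n_dup)
    logger.info("read %d points / %d cells from %s%s",
                len(table.df), table.n_cells, path, " (2D)" if is_2d else "")
    return table


def read_categories(path: str | Path) -> CategoryMap:
    """Read a two-column (cell_id, category) CSV.

    Duplicate rows with identical labels collapse silently; conflicting
    labels for one cell are a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"categories file not found: {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if raw.shape[1] < 2:
        raise FormatError("categories file must have two columns: cell_id, category")
    ids = _numeric(raw.iloc[:, 0], raw.columns[0])
    if not np.all(ids == np.round(ids)):
        raise ParseError("category cell IDs must be integers")
    labels = raw.iloc[:, 1].astype(str).str.strip()
    mapping: dict[int, str] = {}
    for cid, label in zip(ids.astype(int), labels):
        if cid in mapping and mapping[cid] != label:
            raise ValidationError(
                f"cell {cid} is annotated with conflicting categories "
                f"{mapping[cid]!r} and {label!r}"
            )
        mapping[int(cid)] = label
    return CategoryMap(mapping)


def _write_sheets(sheets: dict[str, pd.DataFrame], path: str | Path, order: list[str]) -> None:
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name in order:
            if name in sheets and sheets[name] is not None:
                sheets[name].to_excel(writer, sheet_name=name, index=False)
    logger.info("wrote workbook %s (%d sheets)", path, sum(1 for n in order if n in sheets))


def write_results_workbook(sheets: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Write the main multi-sheet results workbook.

    ``sheets`` maps sheet names (a subset of :data:`MAIN_SHEETS`) to
    frames; the contact sheets are present only when contact detection
    ran. The input CSVs are untouched — results always go to new files.
    """
    unknown = set(sheets) - set(MAIN_SHEETS)
    if unknown:
        raise ValidationError(f"unknown result sheets: {sorted(unknown)}")
    _write_sheets(sheets, path, MAIN_SHEETS)


def write_pca_workbook(sheets: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Write the separate PCA workbook (loadings, variance, scores, tests)."""
    unknown = set(sheets) - set(PCA_SHEETS)
    if unknown:
        raise ValidationError(f"unknown PCA sheets: {sorted(unknown)}")
    _write_sheets(sheets, path, PCA_SHEETS)


def export_sheets_csv(sheets: dict[str, pd.DataFrame], prefix: str | Path) -> list[Path]:
    """Export every sheet as ``<prefix>_<Sheet>.csv`` for headless use."""
    written = []
    for name, df in sheets.items():
        if df is None:
            continue
        out = Path(f"{prefix}_{name}.csv")
        df.to_csv(out, index=False)
        written.append(out)
    return written
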