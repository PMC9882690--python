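"""End-to-end orchestration: repair → step metrics → summaries →
optional contacts → optional PCA, plus workbook/CSV output."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import contacts as contacts_mod
from . import io_tracks, preprocess, stepwise, subset_stats, summary
from .config import RunConfig
from .exceptions import ValidationError
from .io_tracks import CategoryMap, TrackTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one analysis run computes, in memory."""

    table: TrackTable
    steps: pd.DataFrame
    summaries: pd.DataFrame
    tau_aggregates: pd.DataFrame
    contacts_raw: list = field(default_factory=list)
    contacts_filtered: list = field(default_factory=list)
    contact_summary: pd.DataFrame | None = None
    pca: subset_stats.PcaResult | None = None
    group_tests: list = field(default_factory=list)
    pca_labels: pd.Series | None = None

    def main_sheets(self) -> dict[str, pd.DataFrame]:
        sheets = {
            "Formatted_Data": self.table.df,
            "Step_Metrics": self.steps,
            "Summary_Statistics": self.summaries,
            "MSD": summary.msd_table(
                self.summaries,
                sum(c.startswith("msd_") for c in self.summaries.columns),
            ),
            "Tau_Aggregates": self.tau_aggregates,
        }
        if self.contact_summary is not None:
            raw = contacts_mod.events_to_frame(self.contacts_raw)
            kept = {
                (e.cell_a, e.cell_b, e.t_start) for e in self.contacts_filtered
            }
            raw["kept_after_filters"] = [
                (r.cell_a, r.cell_b, r.t_start) in kept for r in raw.itertuples()
            ]
            sheets["Contacts"] = raw
            sheets["Contact_Summary"] = self.contact_summary
        return sheets

    def pca_sheets(self) -> dict[str, pd.DataFrame] | None:
        if self.pca is None:
            return None
        return subset_stats.pca_sheets(self.pca, self.pca_labels, self.group_tests)


def analyze(table: TrackTable, config: RunConfig,
            categories: CategoryMap | None = None) -> PipelineResult:
    """Run the full in-memory analysis on an already-loaded track table."""
    if categories is not None:
        categories.validate_against(table)
    repaired = preprocess.preprocess(
        table, interpolate=config.interpolate, flatten=config.flatten_to_2d
    )
    steps = stepwise.compute_steps(repaired, config)
    summaries = summary.summarize_tracks(repaired, steps, config)
    tau_agg = summary.aggregate_tau(steps, categories, tau_max=config.tau_max)
    result = PipelineResult(
        table=repaired, steps=steps, summaries=summaries, tau_aggregates=tau_agg
    )

    if config.enable_contacts:
        raw = contacts_mod.detect_contacts(repaired, config.contact_limit)
        filtered = contacts_mod.filter_divisions(raw)
        filtered = contacts_mod.filter_dead(filtered, summaries, config.arrest_limit)
        result.contacts_raw = raw
        result.contacts_filtered = filtered
        result.contact_summary = contacts_mod.summarize_contacts(filtered, repaired)

    if config.enable_pca:
        if categories is None or len(categories) == 0:
            logger.warning(
                "PCA requested but no categories were provided; PCA stage skipped"
            )
        else:
            matrix, labels = subset_stats.build_feature_matrix(
                summaries, categories, features=config.pca_features
            )
            result.pca = subset_stats.run_pca(
                matrix, variance_threshold=config.pca_variance_threshold
            )
            result.pca_labels = labels
            result.group_tests = subset_stats.compare_groups(
                result.pca, labels, adjustment=config.dunn_adjustment
            )
    return result


def run_pipeline(config: RunConfig, tracks_path, categories_path=None,
                 output_prefix="trackforge_results", write_csv: bool = False,
                 ) -> PipelineResult:
    """File-to-file run: read inputs, analyze, write workbooks.

    Writes ``<prefix>.xlsx`` and, when PCA ran, ``<prefix>_pca.xlsx``;
    with ``write_csv`` every sheet is also exported as CSV. The input
    files are never modified. Every configuration value is logged so a
    run can be reproduced exactly.
    """
    for key, value in config.describe().items():
        logger.info("config %s = %r", key, value)
    table = io_tracks.read_tracks(tracks_path, config.column_names)
    categories = None
    if categories_path is not None:
        categories = io_tracks.read_categories(categories_path)
    result = analyze(table, config, categories)

    prefix = Path(output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sheets = result.main_sheets()
    io_tracks.write_results_workbook(sheets, prefix.with_suffix(".xlsx"))
    if write_csv:
        io_tracks.export_sheets_csv(sheets, prefix)
    pca_sheets = result.pca_sheets()
    if pca_sheets is not None:
        io_tracks.write_pca_workbook(pca_sheets, Path(f"{prefix}_pca.xlsx"))
        if write_csv:
            io_tracks.export_sheets_csv(pca_sheets, f"{prefix}_pca")
    return result
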