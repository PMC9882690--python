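"""Run configuration: the user-adjustable variables of an analysis run.

Every threshold that shapes the science is held here so a run can be
reproduced from the logged configuration alone. Times and lengths stay
in the user's units (typically seconds/minutes and micrometres); no unit
conversion is attempted anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .exceptions import ValidationError

#: Default CSV header mapping; matching is case-insensitive.
DEFAULT_COLUMNS: dict[str, str] = {
    "cell_id": "ID",
    "t": "T",
    "x": "X",
    "y": "Y",
    "z": "Z",
}


@dataclass
class RunConfig:
    """User-adjustable variables for a full analysis run.

    Parameters
    ----------
    tau_max
        Largest time lag (in frame intervals) for lagged Euclidean
        distances, turning angles and MSD. Lags longer than a track are
        simply absent for that cell.
    min_displacement
        Per-timepoint minimum displacement limit (length units). Steps
        below it count toward the arrest coefficient, and lagged
        distances/turning angles whose legs move less than
        ``min_displacement * tau`` are omitted as background jitter.
    contact_limit
        Centroid distance (length units) strictly below which two cells
        are in contact at a timepoint.
    arrest_limit
        Arrest-coefficient fraction strictly above which a cell is
        considered non-motile and its contacts are discarded.
    flatten_to_2d
        Zero out the Z coordinate before any calculation.
    interpolate
        Fill internal track gaps by per-coordinate linear interpolation.
    enable_contacts, enable_pca
        Optional pipeline stages; both off by default.
    column_names
        Mapping from canonical field names (cell_id/t/x/y/z) to the CSV
        headers of the input file.
    pca_variance_threshold
        Cumulative explained-variance fraction that fixes how many
        principal components are retained for the group tests.
    dunn_adjustment
        Multiple-testing adjustment for Dunn pairwise p-values:
        ``"bonferroni"`` (default), ``"holm"`` or ``"none"``.
    pca_features
        Optional subset of summary-feature columns to feed into PCA;
        ``None`` uses every per-cell scalar feature.
    """

    tau_max: int = 10
    min_displacement: float = 0.0
    contact_limit: float = 12.0
    arrest_limit: float = 0.95
    flatten_to_2d: bool = False
    interpolate: bool = True
    enable_contacts: bool = False
    enable_pca: bool = False
    column_names: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    pca_variance_threshold: float = 0.90
    dunn_adjustment: str = "bonferroni"
    pca_features: list[str] | None = None

    def __post_init__(self) -> None:
        if int(self.tau_max) != self.tau_max or self.tau_max < 1:
            raise ValidationError(f"tau_max must be an integer >= 1, got {self.tau_max}")
        self.tau_max = int(self.tau_max)
        if self.min_displacement < 0:
            raise ValidationError("min_displacement must be >= 0")
        if self.contact_limit <= 0:
            raise ValidationError("contact_limit must be > 0")
        if not 0.0 <= self.arrest_limit <= 1.0:
            raise ValidationError("arrest_limit must lie in [0, 1]")
        if not 0.0 < self.pca_variance_threshold <= 1.0:
            raise ValidationError("pca_variance_threshold must lie in (0, 1]")
        if self.dunn_adjustment not in ("bonferroni", "holm", "none"):
            raise ValidationError(
                f"dunn_adjustment must be bonferroni/holm/none, got {self.dunn_adjustment!r}"
            )
        missing = set(DEFAULT_COLUMNS) - set(self.column_names)
        # z may be omitted entirely for 2D inputs
        missing.discard("z")
        if missing:
            raise ValidationError(f"column_names lacks mappings for: {sorted(missing)}")

    def describe(self) -> dict[str, object]:
        """All configuration values, for logging and reproduction."""
        return {f.name: getattr(self, f.name) for f in fields(self)}
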