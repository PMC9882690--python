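"""PCA-based comparison of annotated cell subsets.

Per-cell summary features (lengths, ratios, angle and velocity
statistics, per-τ MSD values) have incommensurate units, so each feature
column is z-scored before PCA. Components are retained up to a
cumulative explained-variance threshold (default 90%), and for each
retained component the category groups are compared with a
Kruskal-Wallis rank test followed by Dunn's pairwise post-hoc z-tests
(Bonferroni-adjusted by default). Rank tests make no normality
assumption — appropriate because motility features are typically heavy
tailed.

Loadings signs are fixed (largest-magnitude entry of each component
positive) so results are reproducible across runs and BLAS builds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .exceptions import ValidationError
from .io_tracks import CategoryMap

logger = logging.getLogger(__name__)

#: summary columns that never enter the feature matrix
_NON_FEATURES = {"cell_id", "n_points"}


@dataclass
class PcaResult:
    feature_names: list[str]
    loadings: np.ndarray          # features × components, orthonormal columns
    explained_variance_ratio: np.ndarray  # all components; sums to 1
    scores: np.ndarray            # cells × components
    retained_k: int
    cell_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class GroupTestResult:
    component: int                # 1-based index of the principal component
    kruskal_h: float
    kruskal_p: float
    dunn_p: pd.DataFrame          # categories × categories, adjusted p-values
    groups: list[str] = field(default_factory=list)


def build_feature_matrix(
    summaries: pd.DataFrame,
    categories: CategoryMap,
    features: list[str] | None = None,
    min_cells_per_category: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Standardized (z-scored) per-cell feature matrix for annotated cells.

    Rows are annotated cells with complete features; columns are the
    per-cell scalar features. Zero-variance columns are dropped (they
    carry no information and break standardization), as are cells with
    any missing feature — both with a logged warning. Requires at least
    two categories with ``min_cells_per_category`` usable cells each.

    Returns ``(matrix, labels)`` with aligned indices (cell IDs).
    """
    cols = features or [c for c in summaries.columns if c not in _NON_FEATURES]
    unknown = set(cols) - set(summaries.columns)
    if unknown:
        raise ValidationError(f"unknown feature columns requested: {sorted(unknown)}")

    df = summaries.set_index("cell_id")[cols]
    labels = pd.Series({cid: categories.get(cid) for cid in df.index}, name="category")
    annotated = labels.dropna().index
    df = df.loc[annotated]
    labels = labels.loc[annotated]

    incomplete = df.index[df.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("dropping %d cells with missing features: %s",
                       len(incomplete), list(incomplete[:10]))
        df = df.drop(index=incomplete)
        labels = labels.drop(index=incomplete)

    sd = df.std(ddof=0)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        logger.warning("dropping %d zero-variance features: %s",
                       len(constant), list(constant))
        df = df.drop(columns=constant)
        sd = sd.drop(index=constant)

    counts = labels.value_counts()
    usable = counts[counts >= min_cells_per_category]
    if len(usable) < 2:
        raise ValidationError(
            f"need >= 2 categories with >= {min_cells_per_category} complete cells; "
            f"got {counts.to_dict()}"
        )
    if df.shape[1] == 0:
        raise ValidationError("no informative features remain after filtering")

    z = (df - df.mean()) / sd
    return z, labels


def run_pca(matrix: pd.DataFrame | np.ndarray,
            variance_threshold: float = 0.90,
            cell_ids: np.ndarray | None = None) -> PcaResult:
    """PCA of a column-standardized feature matrix.

    ``retained_k`` is the smallest number of leading components whose
    cumulative explained variance reaches the threshold. Loadings
    columns are orthonormal; signs are fixed deterministically.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        if cell_ids is None:
            cell_ids = matrix.index.to_numpy()
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = [f"feature_{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 rows and 2 columns")
    if not np.any(np.std(X, axis=0) > 0):
        raise ValidationError("feature matrix has rank 0; PCA is undefined")

    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features × components

    # deterministic sign: largest-|loading| entry of each component is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    evr = pca.explained_variance_ratio_
    retained_k = int(np.searchsorted(np.cumsum(evr), variance_threshold - 1e-12) + 1)
    retained_k = min(retained_k, len(evr))
    return PcaResult(
        feature_names=names,
        loadings=loadings,
        explained_variance_ratio=evr,
        scores=scores,
        retained_k=retained_k,
        cell_ids=np.asarray(cell_ids) if cell_ids is not None else np.arange(X.shape[0]),
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and p-value across >= 2 groups."""
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_test(groups: list[np.ndarray], labels: list[str],
              adjustment: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise post-hoc z-tests on pooled ranks.

    For groups i, j with mean ranks R̄ᵢ, R̄ⱼ over the pooled sample of
    size N, the statistic is

        z = (R̄ᵢ − R̄ⱼ) / sqrt( (N(N+1)/12 − ΣT/(12(N−1))) · (1/nᵢ + 1/nⱼ) )

    where ΣT = Σ(t³ − t) over tie groups. Two-sided p-values are
    adjusted across all pairs (Bonferroni, Holm, or none) and returned
    as a symmetric matrix with unit diagonal, clipped to [0, 1].
    """
    if adjustment not in ("bonferroni", "holm", "none"):
        raise ValidationError(f"unknown adjustment {adjustment!r}")
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))

    pairs = list(itertools.combinations(range(len(groups)), 2))
    raw = []
    for i, j in pairs:
        se = np.sqrt(var_factor * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw.append(2.0 * stats.norm.sf(abs(z)))
    raw = np.asarray(raw)

    if adjustment == "bonferroni":
        adj = np.minimum(raw * len(pairs), 1.0)
    elif adjustment == "holm":
        order = np.argsort(raw)
        adj = np.empty_like(raw)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, raw[idx] * (len(pairs) - rank))
            adj[idx] = min(running, 1.0)
    else:
        adj = raw

    mat = pd.DataFrame(np.eye(len(groups)), index=labels, columns=labels)
    np.fill_diagonal(mat.values, 1.0)
    for (i, j), p in zip(pairs, adj):
        mat.iat[i, j] = mat.iat[j, i] = p
    return mat


def compare_groups(pca: PcaResult, labels: pd.Series,
                   adjustment: str = "bonferroni",
                   min_cells_per_category: int = 3) -> list[GroupTestResult]:
    """Kruskal-Wallis + Dunn tests per retained principal component.

    Categories with fewer than ``min_cells_per_category`` cells are
    excluded with a warning; if fewer than two remain, tests are skipped
    entirely.
    """
    labels = labels.astype(str)
    counts = labels.value_counts()
    usable = sorted(counts[counts >= min_cells_per_category].index)
    dropped = sorted(set(counts.index) - set(usable))
    if dropped:
        logger.warning("categories excluded from tests (too few cells): %s", dropped)
    if len(usable) < 2:
        logger.warning("fewer than 2 usable categories; group tests skipped")
        return []

    results = []
    label_arr = labels.to_numpy()
    for comp in range(pca.retained_k):
        scores = pca.scores[:, comp]
        groups = [scores[label_arr == cat] for cat in usable]
        h, p = kruskal_wallis(groups)
        results.append(
            GroupTestResult(
                component=comp + 1,
                kruskal_h=h,
                kruskal_p=p,
                dunn_p=dunn_test(groups, usable, adjustment=adjustment),
                groups=usable,
            )
        )
    return results


def pca_sheets(pca: PcaResult, labels: pd.Series,
               tests: list[GroupTestResult]) -> dict[str, pd.DataFrame]:
    """Assemble the PCA workbook sheets."""
    comp_names = [f"PC{i + 1}" for i in range(pca.loadings.shape[1])]
    loadings = pd.DataFrame(pca.loadings, index=pca.feature_names, columns=comp_names)
    loadings = loadings.reset_index(names="feature")
    variance = pd.DataFrame(
        {
            "component": comp_names,
            "explained_variance_ratio": pca.explained_variance_ratio,
            "cumulative": np.cumsum(pca.explained_variance_ratio),
            "retained": [i < pca.retained_k for i in range(len(comp_names))],
        }
    )
    scores = pd.DataFrame(pca.scores, columns=comp_names)
    scores.insert(0, "cell_id", pca.cell_ids)
    scores.insert(1, "category", labels.reindex(pca.cell_ids).to_numpy())

    kw = pd.DataFrame(
        [
            {"component": f"PC{t.component}", "kruskal_H": t.kruskal_h,
             "kruskal_p": t.kruskal_p}
            for t in tests
        ],
        columns=["component", "kruskal_H", "kruskal_p"],
    )
    dunn_rows = []
    for t in tests:
        for a, b in itertools.combinations(t.groups, 2):
            dunn_rows.append(
                {"component": f"PC{t.component}", "group_a": a, "group_b": b,
                 "p_adjusted": t.dunn_p.loc[a, b]}
            )
    dunn = pd.DataFrame(dunn_rows, columns=["component", "group_a", "group_b", "p_adjusted"])
    return {
        "Loadings": loadings,
        "Explained_Variance": variance,
        "Scores": scores,
        "KW_Tests": kw,
        "Dunn_Pairwise": dunn,
    }
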