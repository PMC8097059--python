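"""Normalization, filtering, ratio construction and descriptive projections.

These are the steps applied to a log2 quantification matrix before any
significance testing: per-sample median centering, group-completeness
filtering, log2 ratios against a reference group's row median, row z-scaling
for display, PCA and two-metric hierarchical clustering (Canberra distance
on rows, 1 − Pearson correlation on columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform

from .io import QuantMatrix, SampleDesign

__all__ = [
    "NormalizationReport",
    "normalize_median_center",
    "filter_by_completeness",
    "make_log2_ratios_vs_reference",
    "scale_rows_z",
    "run_pca",
    "hierarchical_cluster",
    "PcaResult",
    "ClusterResult",
]


@dataclass
class NormalizationReport:
    method: str
    median_before: pd.Series
    median_after: pd.Series


def normalize_median_center(matrix: QuantMatrix) -> tuple[QuantMatrix, NormalizationReport]:
    """Shift each sample column so its median over observed values is 0."""
    data = matrix.data
    n_obs = data.notna().sum(axis=0)
    if (n_obs == 0).any():
        empty = n_obs.index[n_obs == 0].tolist()
        raise ValueError(f"sample(s) with no observed values: {empty}")
    before = data.median(axis=0, skipna=True)
    centered = data.sub(before, axis=1)
    after = centered.median(axis=0, skipna=True)
    report = NormalizationReport("median_center", before, after)
    return QuantMatrix(centered, matrix.feature_kind), report


def filter_by_completeness(
    matrix: QuantMatrix,
    design: SampleDesign,
    min_per_group: int,
    conditions: list[str] | None = None,
) -> QuantMatrix:
    """Keep rows observed at least ``min_per_group`` times in every group.

    ``conditions`` restricts the requirement to a subset of conditions
    (default: every condition in the design).
    """
    if min_per_group < 1:
        raise ValueError("min_per_group must be >= 1")
    conditions = conditions if conditions is not None else design.conditions
    keep = pd.Series(True, index=matrix.data.index)
    for cond in conditions:
        cols = design.samples(cond)
        keep &= matrix.data[cols].notna().sum(axis=1) >= min_per_group
    if not keep.any():
        warnings.warn("completeness filter removed every feature")
    return QuantMatrix(matrix.data.loc[keep], matrix.feature_kind)


def make_log2_ratios_vs_reference(
    matrix: QuantMatrix,
    design: SampleDesign,
    reference_condition: str,
    case_conditions: list[str] | None = None,
) -> QuantMatrix:
    """Per-row log2 ratios of case samples against the reference row median.

    Each case sample value minus the row-wise median of the reference group;
    rows without any observed reference value get all-missing ratios.
    """
    ref_cols = design.samples(reference_condition)
    if case_conditions is None:
        case_conditions = [c for c in design.conditions if c != reference_condition]
    case_cols = [s for c in case_conditions for s in design.samples(c)]
    ref_median = matrix.data[ref_cols].median(axis=1, skipna=True)
    ratios = matrix.data[case_cols].sub(ref_median, axis=0)
    return QuantMatrix(ratios, matrix.feature_kind)


def scale_rows_z(matrix: QuantMatrix) -> QuantMatrix:
    """Scale each row to mean 0, SD 1 (n−1 denominator) over observed entries.

    Rows with fewer than 2 observed values or zero SD are dropped with a
    warning; intended for display/clustering, not for testing.
    """
    data = matrix.data
    mean = data.mean(axis=1, skipna=True)
    sd = data.std(axis=1, ddof=1, skipna=True)
    ok = (data.notna().sum(axis=1) >= 2) & (sd > 0)
    if (~ok).any():
        warnings.warn(f"dropped {(~ok).sum()} constant/underobserved rows in z-scaling")
    scaled = data.loc[ok].sub(mean[ok], axis=0).div(sd[ok], axis=0)
    return QuantMatrix(scaled, matrix.feature_kind)


@dataclass
class PcaResult:
    scores: pd.DataFrame         # samples × components
    loadings: pd.DataFrame       # features × components
    explained_variance: np.ndarray
    n_features_used: int
    n_features_dropped: int


def run_pca(matrix: QuantMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples over complete features (rows with missing values dropped).

    Components are ordered by decreasing variance.  Sign convention: within
    each component the largest-magnitude loading is positive.
    """
    data = matrix.data.dropna(axis=0)
    n_dropped = matrix.shape[0] - data.shape[0]
    if data.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if data.shape[0] < 1:
        raise ValueError("no complete features available for PCA")
    X = data.to_numpy().T  # samples × features
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(X.shape) if n_components is None else min(n_components, min(X.shape))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # fix signs so the largest-|loading| entry of each component is positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    u, vt = u * flip, vt * flip[:, None]
    expl = s**2 / max(X.shape[0] - 1, 1)
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=data.columns, columns=cols)
    loadings = pd.DataFrame(vt.T, index=data.index, columns=cols)
    return PcaResult(scores, loadings, expl, data.shape[0], n_dropped)


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """Condensed 1 − Pearson correlation distances between columns of X."""
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance column under the Pearson metric")
    r = np.corrcoef(X.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0  # clip tiny negative rounding artifacts
    return squareform(d, checks=False)


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def hierarchical_cluster(
    matrix: QuantMatrix,
    row_metric: str = "canberra",
    col_metric: str = "pearson",
    linkage_method: str = "average",
) -> ClusterResult:
    """Two-way agglomerative clustering of a complete matrix.

    Defaults follow the heatmap convention used throughout the analysis:
    Canberra distance on rows and 1 − Pearson correlation on columns with
    average linkage.  Leaf orders are deterministic (scipy's ordering).
    """
    data = matrix.data
    if data.isna().any().any():
        raise ValueError("clustered submatrix must not contain missing values")
    X = data.to_numpy()

    def _condensed(mat: np.ndarray, metric: str) -> np.ndarray:
        if metric == "pearson":
            return _pearson_distance(mat)
        return pdist(mat.T, metric=metric)

    if linkage_method != "average":
        raise ValueError("only average linkage is supported")
    row_link = average(_condensed(X.T, row_metric))
    col_link = average(_condensed(X, col_metric))
    row_order = [data.index[i] for i in leaves_list(row_link)]
    col_order = [data.columns[i] for i in leaves_list(col_link)]
    return ClusterResult(row_order, col_order, row_link, col_link)
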