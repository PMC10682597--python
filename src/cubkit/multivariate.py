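"""Multivariate analysis of codon usage: PCA of RSCU profiles, clustering on
PCA scores and clustered heatmap matrices.

Rows are organisms by default (organism-mean RSCU, parasites plus the
host), so each organism is one point in codon usage space; per-sequence
rows are supported by passing a per-sequence RSCU table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import nan_euclidean_distances

from .genetics import DEFAULT_EXCLUDED_CODONS

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # rows x components
    loadings: pd.DataFrame        # codons x components
    variance_explained: np.ndarray  # percentages, sum to 100 over all components


@dataclass
class ClusterAssignment:
    labels: pd.Series  # row -> cluster id (0-based, relabelled by appearance)
    k: int
    method: str
    rank: int
    metric: str = "euclidean"
    linkage: str = "ward.D2"


def build_rscu_matrix(
    parasite_rscu: pd.DataFrame,
    host_rscu: pd.DataFrame | None = None,
    exclusions=DEFAULT_EXCLUDED_CODONS,
) -> pd.DataFrame:
    """Stack parasite (and host) wide RSCU tables and drop excluded codons.

    The default exclusion list {ATG, TAA, TAG, TGA, TGG} is a no-op on the
    59-codon tables produced by :func:`cubkit.cub_indices.rscu_table` but
    is honoured for any further codons the caller excludes.
    """
    frames = [parasite_rscu]
    if host_rscu is not None:
        frames.append(host_rscu)
    mat = pd.concat(frames, axis=0)
    drop = [c for c in exclusions if c in mat.columns]
    mat = mat.drop(columns=drop)
    if mat.shape[1] == 0:
        raise ValueError("exclusion list removed every codon column")
    if mat.isna().any().any():
        logger.warning("RSCU matrix contains missing cells; filled with 0")
        mat = mat.fillna(0.0)
    return mat


def pca_rscu(matrix: pd.DataFrame, center: bool = True,
             scale: bool = False) -> PCAResult:
    """PCA of an RSCU matrix (centered, unscaled by default).

    Component signs are fixed by forcing the largest-magnitude loading of
    each component positive, so scores are reproducible across linear
    algebra backends.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    x = matrix.to_numpy(dtype=float)
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("matrix has no variance; PCA undefined")
    if not center:
        # sklearn always centers; emulate uncentered PCA via SVD would
        # change semantics, so centering is required here
        raise NotImplementedError("uncentered PCA is not supported")
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = x / sd
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # codons x components
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_ * 100.0,
    )


def _hclust_labels(points: np.ndarray, k: int, metric: str,
                   linkage_name: str) -> np.ndarray:
    dist = pdist(points, metric=metric)
    if linkage_name == "ward.D":
        # Ward on squared dissimilarities (R's hclust ward.D convention)
        z = hierarchy.linkage(dist ** 2, method="ward")
    elif linkage_name == "ward.D2":
        z = hierarchy.linkage(dist, method="ward")
    else:
        z = hierarchy.linkage(dist, method=linkage_name)
    return hierarchy.fcluster(z, t=k, criterion="maxclust")


def cluster_on_pca(
    pca: PCAResult,
    k: int,
    rank: int = 2,
    method: str = "kmeans",
    metric: str = "euclidean",
    linkage: str = "ward.D2",
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster rows on the first ``rank`` PCA score dimensions.

    kmeans runs with multiple restarts under the given seed; hierarchical
    clustering accepts the R naming "ward.D" / "ward.D2" as well as scipy
    linkage names, with the chosen distance metric.
    """
    n = pca.scores.shape[0]
    if not 1 <= rank <= pca.scores.shape[1]:
        raise ValueError(f"rank must be in [1, {pca.scores.shape[1]}]")
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    pts = pca.scores.iloc[:, :rank].to_numpy()
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
        raw = km.fit_predict(pts)
    elif method == "hierarchical":
        raw = _hclust_labels(pts, k, metric, linkage)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    # relabel clusters by order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        labels[i] = remap.setdefault(int(lab), len(remap))
    return ClusterAssignment(
        labels=pd.Series(labels, index=pca.scores.index, name="cluster"),
        k=k, method=method, rank=rank, metric=metric, linkage=linkage,
    )


@dataclass
class HeatmapMatrix:
    values: pd.DataFrame
    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def heatmap_matrix(
    values: pd.DataFrame,
    average_per_organism: bool = False,
    cluster_rows: bool = True,
    cluster_cols: bool = True,
    metric: str = "euclidean",
    linkage: str = "ward.D2",
) -> HeatmapMatrix:
    """Prepare an RSCU or dinucleotide z-score matrix for heatmap display.

    Rows collapse to organism means when ``average_per_organism`` (the index
    must then carry the organism as its first level).  Undefined cells
    (NaN, e.g. degenerate z-scores) are excluded pairwise from distances;
    all-NaN rows are dropped with a warning.
    """
    mat = values.copy()
    if average_per_organism:
        level = mat.index.names[0] if mat.index.nlevels > 1 else None
        if level is not None:
            mat = mat.groupby(level=level, sort=False).mean()
    all_nan = mat.isna().all(axis=1)
    if all_nan.any():
        logger.warning("dropping %d all-undefined rows from heatmap",
                       int(all_nan.sum()))
        mat = mat.loc[~all_nan]

    def _order(df: pd.DataFrame):
        x = df.to_numpy(dtype=float)
        if x.shape[0] < 2:
            return list(range(x.shape[0])), None
        if np.isnan(x).any():
            dist = squareform(nan_euclidean_distances(x), checks=False)
        else:
            dist = pdist(x, metric=metric)
        if linkage == "ward.D":
            z = hierarchy.linkage(dist ** 2, method="ward")
        elif linkage == "ward.D2":
            z = hierarchy.linkage(dist, method="ward")
        else:
            z = hierarchy.linkage(dist, method=linkage)
        return hierarchy.leaves_list(z).tolist(), z

    row_order = list(range(mat.shape[0]))
    col_order = list(range(mat.shape[1]))
    row_z = col_z = None
    if cluster_rows:
        row_order, row_z = _order(mat)
    if cluster_cols:
        col_order, col_z = _order(mat.T)
    return HeatmapMatrix(
        values=mat,
        row_order=[mat.index[i] for i in row_order],
        col_order=[mat.columns[i] for i in col_order],
        row_linkage=row_z,
        col_linkage=col_z,
    )
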