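"""Screen-level multivariate analytics of compound behavioral profiles.

The compound x 25-parameter matrix of DMSO-standardized means is analyzed
with centered (unscaled) PCA — the 25 measures are already on comparable
percentage-point scales and receive equal weight.  K-means runs on the
retained principal axes (smallest number of components reaching 85 %
cumulative explained variance), with the cluster count chosen by the average
silhouette width; agglomerative clustering uses Euclidean distances with
Ward's minimum-variance linkage on the raw 25-parameter space.  The cluster
containing the calcineurin-inhibitor reference compounds (CsA, FK506)
defines the "CsA-type" profile used to flag candidate compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .behavior_profile import PARAMETERS
from .errors import InputError

VARIANCE_RETAINED_PCT = 85.0
DEFAULT_K_RANGE = range(2, 11)
DEFAULT_N_RESTARTS = 25


@dataclass
class PCAResult:
    """Centered PCA of the screen matrix."""

    scores: pd.DataFrame        # compounds x components (Dim1, Dim2, ...)
    loadings: pd.DataFrame      # parameters x components
    explained_pct: np.ndarray   # per-component explained variance, percent
    mean: pd.Series             # column means removed before rotation

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.explained_pct)

    def n_components_for(self, pct: float = VARIANCE_RETAINED_PCT) -> int:
        """Smallest component count whose cumulative explained variance >= pct."""
        reached = np.flatnonzero(self.cumulative_pct >= pct - 1e-9)
        return int(reached[0]) + 1 if len(reached) else len(self.explained_pct)


@dataclass
class ClusterResult:
    """A clustering of the screen matrix compounds."""

    method: str                  # "kmeans" | "ward"
    k: int
    labels: pd.Series            # compound -> cluster id (1-based)
    means: pd.DataFrame          # cluster x 25-parameter means (original space)
    reference_cluster: int | None = None
    linkage: np.ndarray | None = None        # ward only
    leaf_order: list[str] = field(default_factory=list)  # ward only


def _clean_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Impute missing cells as 0 (DMSO-like) — the standardized neutral value."""
    if matrix.isna().any().any():
        n = int(matrix.isna().sum().sum())
        warnings.warn(f"imputing {n} missing screen-matrix cells as 0 (DMSO-like)")
        matrix = matrix.fillna(0.0)
    return matrix


def pca_profiles(matrix: pd.DataFrame, scale: bool = False) -> PCAResult:
    """Centered PCA of the compound x parameter matrix.

    With ``scale`` the columns are additionally divided by their standard
    deviation (off by default: equal weight on the common percentage-point
    scale).  Explained-variance percents sum to 100 over all components.
    """
    if len(matrix) < 2:
        raise InputError("PCA needs at least 2 compounds")
    matrix = _clean_matrix(matrix)
    X = matrix.to_numpy(float)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    comps = [f"Dim{i + 1}" for i in range(pca.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comps),
        loadings=pd.DataFrame(pca.components_.T, index=matrix.columns, columns=comps),
        explained_pct=100.0 * pca.explained_variance_ratio_,
        mean=pd.Series(pca.mean_, index=matrix.columns),
    )


def choose_k_silhouette(
    scores: pd.DataFrame | np.ndarray,
    k_range: range = DEFAULT_K_RANGE,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> int:
    """Cluster count maximizing the average silhouette width over K-means fits."""
    X = np.asarray(scores, dtype=float)
    if np.allclose(X, X[0]):
        raise InputError("all compound scores identical; silhouette undefined")
    best_k, best_width = None, -np.inf
    for k in k_range:
        if k >= len(X):
            break
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        if len(np.unique(km.labels_)) < 2:
            continue
        width = silhouette_score(X, km.labels_)
        if width > best_width:
            best_k, best_width = k, width
    if best_k is None:
        raise InputError("no k in range produced a valid clustering")
    return best_k


def kmeans_clusters(
    scores: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
    matrix: pd.DataFrame | None = None,
) -> ClusterResult:
    """K-means on the (PCA-score) rows; cluster means reported in profile space.

    ``matrix`` supplies the original 25-parameter rows used for the reported
    cluster means; when omitted the means are taken over the score space.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    if k > len(scores):
        raise InputError(f"k={k} exceeds {len(scores)} compounds")
    X = np.asarray(scores, dtype=float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    labels = pd.Series(km.labels_ + 1, index=scores.index, name="cluster")
    source = matrix if matrix is not None else scores
    means = source.groupby(labels).mean()
    means.index.name = "cluster"
    return ClusterResult(method="kmeans", k=k, labels=labels, means=means)


def hierarchical_clusters(matrix: pd.DataFrame, k: int) -> ClusterResult:
    """Agglomerative clustering: Euclidean distance, Ward minimum-variance linkage.

    All 25 parameters enter with equal weight.  The tree is cut at ``k``
    clusters; the dendrogram leaf order (heatmap row order) and the linkage
    matrix are kept on the result for export.
    """
    if len(matrix) < k:
        raise InputError(f"{len(matrix)} compounds cannot form {k} clusters")
    matrix = _clean_matrix(matrix)
    X = matrix.to_numpy(float)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=matrix.index, name="cluster")
    means = matrix.groupby(labels).mean()
    means.index.name = "cluster"
    order = [matrix.index[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(method="ward", k=int(labels.max()), labels=labels,
                         means=means, linkage=Z, leaf_order=order)


def identify_reference_cluster(result: ClusterResult, references: list[str]
                               ) -> int | None:
    """The cluster housing all reference compounds; None (with a warning) if split."""
    missing = [r for r in references if r not in result.labels.index]
    if missing:
        raise InputError(f"reference compounds not in matrix: {missing}")
    clusters = {int(result.labels[r]) for r in references}
    if len(clusters) != 1:
        warnings.warn(f"reference compounds split across clusters {sorted(clusters)}")
        result.reference_cluster = None
        return None
    (cluster,) = clusters
    result.reference_cluster = cluster
    return cluster


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = build(node.get_left(), node.dist)
        right = build(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"


def export_cluster_results(result: ClusterResult, out_dir: str | Path,
                           prefix: str = "clusters") -> None:
    """Write membership CSV (and the Ward dendrogram as Newick when present)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    member = result.labels.rename_axis("treatment").reset_index()
    member["is_reference_cluster"] = member["cluster"] == result.reference_cluster
    member.to_csv(out_dir / f"{prefix}_{result.method}.csv", index=False)
    result.means.to_csv(out_dir / f"{prefix}_{result.method}_means.csv")
    if result.linkage is not None:
        newick = linkage_to_newick(result.linkage, list(result.labels.index))
        (out_dir / f"{prefix}_ward.nwk").write_text(newick + "\n")
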