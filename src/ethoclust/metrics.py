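"""Cluster Maps and clustering-validity metrics.

``project`` reduces latent vectors (or raw flattened keypoints) to 2-D/3-D
coordinates for display with PCA, t-SNE or UMAP.  Clustering quality of a
representation is quantified with the Calinski-Harabasz index (CHI,
between- over within-cluster dispersion; higher is better) and the
Davies-Bouldin index (DBI, within- over between-cluster scatter; lower is
better), computed from the canonical formulas:

    CHI = [B / (k-1)] / [W / (N-k)],   B = sum_c n_c ||mu_c - mu||^2,
                                       W = sum_c sum_{x in c} ||x - mu_c||^2
    DBI = (1/k) sum_i max_{j != i} (S_i + S_j) / ||mu_i - mu_j||,
                                       S_i = mean ||x - mu_i|| within cluster i

Clustering itself (k-means) runs in the native representation space;
projection is for display only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .model import LatentMatrix

__all__ = [
    "EmbeddingMatrix",
    "ClusterAssignment",
    "project",
    "kmeans_cluster",
    "chi",
    "dbi",
    "metric_sweep",
]


@dataclass
class EmbeddingMatrix:
    """Low-dimensional display coordinates for a set of segments."""

    coords: np.ndarray  # N x d, d in {2, 3}
    method: str
    seed: int
    params: dict | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("embedding must be N x d with d in {2, 3}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")


@dataclass
class ClusterAssignment:
    """Integer cluster labels for N points."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_clusters
        ):
            raise ValueError("labels outside [0, n_clusters)")


def _as_points(points) -> np.ndarray:
    if isinstance(points, LatentMatrix):
        points = points.values
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array (N x features)")
    return pts


def project(points, method: str = "pca", d: int = 2, seed: int = 0) -> EmbeddingMatrix:
    """Reduce N x m points to N x d display coordinates.

    PCA columns are ordered by decreasing explained variance.  t-SNE
    perplexity defaults to 30 clamped to (N-1)/3 for small N; UMAP uses 15
    neighbors (clamped to N-1) and min_dist 0.1.  Deterministic given the
    seed.
    """
    pts = _as_points(points)
    N = pts.shape[0]
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    if method == "pca":
        if N < d + 1:
            raise ValueError(f"pca needs at least {d + 1} points")
        p = PCA(n_components=d, random_state=seed)
        coords = p.fit_transform(pts)
        params = {"explained_variance_ratio": p.explained_variance_ratio_.tolist()}
    elif method == "tsne":
        perplexity = min(30.0, max(1.0, (N - 1) / 3.0))
        t = TSNE(n_components=d, perplexity=perplexity, random_state=seed, init="pca")
        coords = t.fit_transform(pts)
        params = {"perplexity": perplexity}
    elif method == "umap":
        import umap  # heavy import kept local

        n_neighbors = min(15, max(2, N - 1))
        u = umap.UMAP(
            n_components=d, n_neighbors=n_neighbors, min_dist=0.1, random_state=seed
        )
        coords = u.fit_transform(pts)
        params = {"n_neighbors": n_neighbors, "min_dist": 0.1}
    else:
        raise ValueError(f"unknown method {method!r}; expected pca, tsne or umap")
    return EmbeddingMatrix(np.asarray(coords, dtype=np.float64), method, seed, params)


def kmeans_cluster(points, n_clusters: int, seed: int = 0) -> ClusterAssignment:
    """Seeded k-means (k-means++ init, 10 restarts)."""
    pts = _as_points(points)
    if n_clusters < 1 or n_clusters > pts.shape[0]:
        raise ValueError("n_clusters must be in [1, N]")
    if n_clusters == pts.shape[0]:
        # each point its own cluster, ordered by first appearance
        return ClusterAssignment(np.arange(pts.shape[0]), n_clusters)
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed)
    return ClusterAssignment(km.fit_predict(pts), n_clusters)


def _centroids(pts: np.ndarray, assignment: ClusterAssignment):
    k = assignment.n_clusters
    used = np.unique(assignment.labels)
    if used.size != k:
        raise ValueError("every cluster must have at least one member")
    mus = np.stack([pts[assignment.labels == c].mean(axis=0) for c in range(k)])
    sizes = np.bincount(assignment.labels, minlength=k)
    return mus, sizes


def chi(points, assignment: ClusterAssignment) -> float:
    """Calinski-Harabasz index; +inf when within-cluster scatter is zero."""
    pts = _as_points(points)
    k = assignment.n_clusters
    N = pts.shape[0]
    if k < 2:
        raise ValueError("CHI requires at least 2 clusters")
    if N <= k:
        raise ValueError("CHI requires N > n_clusters")
    mus, sizes = _centroids(pts, assignment)
    mu = pts.mean(axis=0)
    B = float((sizes * ((mus - mu) ** 2).sum(axis=1)).sum())
    W = float(((pts - mus[assignment.labels]) ** 2).sum())
    if W == 0.0:
        return np.inf
    return (B / (k - 1)) / (W / (N - k))


def dbi(points, assignment: ClusterAssignment) -> float:
    """Davies-Bouldin index; errors on coincident centroids."""
    pts = _as_points(points)
    k = assignment.n_clusters
    if k < 2:
        raise ValueError("DBI requires at least 2 clusters")
    mus, _ = _centroids(pts, assignment)
    S = np.array(
        [
            np.linalg.norm(pts[assignment.labels == c] - mus[c], axis=1).mean()
            for c in range(k)
        ]
    )
    M = np.linalg.norm(mus[:, None, :] - mus[None, :, :], axis=2)
    off = ~np.eye(k, dtype=bool)
    zero = np.argwhere((M == 0) & off)
    if zero.size:
        i, j = zero[0]
        raise ValueError(f"clusters {i} and {j} have coincident centroids")
    R = (S[:, None] + S[None, :]) / np.where(off, M, np.inf)
    return float(np.max(np.where(off, R, -np.inf), axis=1).mean())


def metric_sweep(
    points_raw,
    points_latent,
    kc_list=None,
    seed: int = 0,
) -> pd.DataFrame:
    """CHI/DBI for both representations over a range of cluster counts.

    Returns a tidy table with columns representation, kc, chi, dbi — one
    row per (representation, kc); default kc range is 2..20 step 2.
    """
    if kc_list is None:
        kc_list = list(range(2, 21, 2))
    rows = []
    for name, pts in (("raw", points_raw), ("latent", points_latent)):
        pts = _as_points(pts)
        for kc in kc_list:
            assign = kmeans_cluster(pts, kc, seed=seed)
            rows.append(
                {
                    "representation": name,
                    "kc": int(kc),
                    "chi": chi(pts, assign),
                    "dbi": dbi(pts, assign),
                }
            )
    return pd.DataFrame(rows, columns=["representation", "kc", "chi", "dbi"])
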