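"""Embedding-analysis suite: displacements, conserved K-NN, ARI, CHI.

These are the statistics used to characterise what contrastive alignment
does to an embedding space: how far each protein's embedding moved
(Euclidean, in the original space), how much of its neighbourhood survived,
and how well the space separates ground-truth categories (K-Means + adjusted
Rand index, Calinski–Harabasz index).

ARI and CHI are computed from their closed-form definitions here;
scikit-learn supplies K-Means and t-SNE (standard steps) and serves as an
independent cross-check for the formulas in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

DEFAULT_KMEANS_RESTARTS = 10


@dataclass
class ClusterEvalReport:
    ari: float
    chi: float
    n_clusters: int
    reduction: str            # {"none", "2d"}
    perplexity: float | None = None


@dataclass
class KnnConservation:
    K: int
    proportion: float


def displacement_distribution(before: np.ndarray, after: np.ndarray) -> np.ndarray:
    """Per-protein Euclidean displacement in the original embedding space."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after shapes differ")
    return np.linalg.norm(after - before, axis=-1)


def _knn_sets(x: np.ndarray, K: int) -> np.ndarray:
    """Indices of each point's K nearest Euclidean neighbours, self excluded.

    Ties broken by index order (stable argsort on the distance row).
    """
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, :K]


def knn_conservation(before: np.ndarray, after: np.ndarray, K: int) -> KnnConservation:
    """Average overlap of K-NN sets computed before vs after a transform."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    n = before.shape[0]
    if not (1 <= K <= n - 1):
        raise ValueError(f"K must be in [1, {n - 1}]")
    nb = _knn_sets(before, K)
    na = _knn_sets(after, K)
    overlaps = [len(set(nb[i]) & set(na[i])) for i in range(n)]
    return KnnConservation(K=K, proportion=float(np.mean(overlaps) / K))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index from the contingency-table formula."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = a.size
    cats_a, inv_a = np.unique(a, return_inverse=True)
    cats_b, inv_b = np.unique(b, return_inverse=True)
    table = np.zeros((cats_a.size, cats_b.size), dtype=np.int64)
    np.add.at(table, (inv_a, inv_b), 1)
    sum_comb = sum(comb(int(nij), 2) for nij in table.ravel())
    sum_a = sum(comb(int(ni), 2) for ni in table.sum(axis=1))
    sum_b = sum(comb(int(nj), 2) for nj in table.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # degenerate: single cluster on both sides
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def calinski_harabasz(embeddings: np.ndarray, labels) -> float:
    """[tr(B)/(k-1)] / [tr(W)/(n-k)] with scatter about label centroids."""
    x = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    cats, inv = np.unique(labels, return_inverse=True)
    n, k = x.shape[0], cats.size
    if k < 2:
        raise ValueError("need at least 2 labels")
    grand = x.mean(axis=0)
    tr_b = tr_w = 0.0
    for c in range(k):
        pts = x[inv == c]
        centroid = pts.mean(axis=0)
        tr_b += pts.shape[0] * float(np.sum((centroid - grand) ** 2))
        tr_w += float(np.sum((pts - centroid) ** 2))
    if tr_w == 0.0:
        raise ValueError("zero within-cluster dispersion")
    return (tr_b / (k - 1)) / (tr_w / (n - k))


def cluster_ari(embeddings: np.ndarray, labels, n_clusters: int | None = None,
                reduce_2d: bool = False, seed: int = 0) -> ClusterEvalReport:
    """K-Means the embeddings (optionally after seeded 2D t-SNE), score vs labels."""
    x = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    if n_clusters is None:
        n_clusters = int(np.unique(labels).size)
    if x.shape[0] < n_clusters:
        raise ValueError("fewer points than clusters")
    perplexity = None
    if reduce_2d:
        perplexity = float(min(30.0, max(2.0, (x.shape[0] - 1) / 3.0)))
        x = TSNE(n_components=2, perplexity=perplexity,
                 random_state=seed, init="pca").fit_transform(x)
    km = KMeans(n_clusters=n_clusters, n_init=DEFAULT_KMEANS_RESTARTS,
                random_state=seed)
    assign = km.fit_predict(x)
    return ClusterEvalReport(
        ari=adjusted_rand_index(assign, labels),
        chi=calinski_harabasz(np.asarray(embeddings, dtype=float), labels),
        n_clusters=n_clusters,
        reduction="2d" if reduce_2d else "none",
        perplexity=perplexity)
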