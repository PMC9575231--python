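"""Clustering, batch-mixing, and cell-similarity metrics for benchmarking.

These are the quantitative readouts used to judge normalization quality:
adjusted Rand index against known cell types, mean silhouette width of
embeddings, K-means and resolution-tuned Louvain clustering, the integration
local inverse Simpson's index (iLISI) for batch mixing, shared-nearest-
neighbor similarity, and cell-type dendrograms from similarity matrices.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("schicnd")


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected partition agreement; 1 iff identical partitions."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def mean_silhouette(embedding: np.ndarray, labels) -> float:
    """Mean silhouette width (Euclidean) of a labeled embedding, in [-1, 1]."""
    return float(silhouette_score(np.asarray(embedding), np.asarray(labels)))


def kmeans_labels(embedding: np.ndarray, k: int, restarts: int = 300,
                  max_iter: int = 1000, seed: int = 0) -> np.ndarray:
    """Best-inertia K-means over many restarts (deterministic given seed)."""
    X = np.asarray(embedding)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of cells")
    km = KMeans(n_clusters=k, n_init=restarts, max_iter=max_iter,
                random_state=seed)
    return km.fit_predict(X)


def _knn_sets(X: np.ndarray, k: int) -> list[set[int]]:
    """k-nearest-neighbor index sets (self included) under Euclidean distance."""
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)
    return [set(row) for row in idx]


def snn_similarity(embedding: np.ndarray, k: int = 20) -> np.ndarray:
    """Shared-nearest-neighbor similarity: Jaccard overlap of kNN sets.

    Symmetric with values in [0, 1]; the diagonal is set to 0 by convention
    (self-similarity carries no information for clustering).
    """
    X = np.asarray(embedding)
    if X.shape[0] <= k:
        raise ValueError("need more cells than k")
    sets = _knn_sets(X, k)
    n = len(sets)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if inter:
                sim[i, j] = sim[j, i] = inter / len(sets[i] | sets[j])
    return sim


def _snn_graph(X: np.ndarray, k: int) -> igraph.Graph:
    sim = snn_similarity(X, k=min(k, X.shape[0] - 1))
    src, dst = np.nonzero(np.triu(sim, 1))
    g = igraph.Graph(n=X.shape[0], edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = sim[src, dst].tolist()
    return g


def louvain_target_k(embedding: np.ndarray, k_target: int,
                     k_neighbors: int = 20, tol_iter: int = 30,
                     seed: int = 0,
                     resolution_range: tuple[float, float] = (1e-3, 10.0),
                     ) -> np.ndarray:
    """Louvain communities on the SNN graph, resolution tuned to ``k_target``.

    The modularity resolution is binary-searched within
    ``resolution_range`` until the community count matches ``k_target`` or
    the iteration budget is spent; the closest-count labeling is returned
    (with a warning when the target is unreachable).
    """
    X = np.asarray(embedding)
    if X.shape[0] <= k_neighbors:
        raise ValueError("need more cells than k_neighbors")
    graph = _snn_graph(X, k_neighbors)
    weights = graph.es["weight"]

    def communities(resolution: float) -> np.ndarray:
        _pyrandom.seed(seed)
        part = graph.community_multilevel(weights=weights,
                                          resolution=resolution)
        return np.asarray(part.membership)

    lo, hi = resolution_range
    best_labels, best_gap = None, None
    for _ in range(tol_iter):
        mid = (lo + hi) / 2.0
        labels = communities(mid)
        n_comm = labels.max() + 1
        gap = abs(n_comm - k_target)
        if best_gap is None or gap < best_gap:
            best_labels, best_gap = labels, gap
        if n_comm == k_target:
            return labels
        if n_comm < k_target:
            lo = mid  # larger resolution -> more communities
        else:
            hi = mid
    logger.warning("louvain: target k=%d unreachable, returning closest "
                   "(off by %d)", k_target, best_gap)
    return best_labels


def ilisi_scores(embedding: np.ndarray, batches, perplexity: float = 30.0,
                 ) -> np.ndarray:
    """Integration local inverse Simpson's index per cell.

    For each cell a Gaussian kernel over the other cells is calibrated so
    the neighborhood entropy equals ``log(perplexity)`` (the t-SNE
    convention); batch probabilities ``p_b`` are kernel-weighted batch
    frequencies and the score is ``1 / sum_b p_b^2``.  Scores live in
    ``[1, B]``: 1 means a single batch dominates the neighborhood, B means
    perfect mixing of B batches.
    """
    X = np.asarray(embedding, dtype=float)
    codes, levels = pd.factorize(np.asarray(batches))
    n, n_batches = X.shape[0], len(levels)
    if n < 2:
        raise ValueError("need >= 2 cells")
    if n_batches == 1:
        return np.ones(n)
    perplexity = min(perplexity, n - 1)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    target = np.log(perplexity)
    scores = np.empty(n)
    for i in range(n):
        di = np.delete(d2[i], i)
        ci = np.delete(codes, i)
        beta_lo, beta_hi = 0.0, np.inf
        beta = 1.0 / (di.mean() + 1e-12)
        for _ in range(60):
            w = np.exp(-beta * di)
            sw = w.sum()
            if sw <= 0:
                entropy = 0.0
            else:
                pr = w / sw
                entropy = -(pr * np.log(pr + 1e-300)).sum()
            if abs(entropy - target) < 1e-5:
                break
            if entropy > target:
                beta_lo = beta
                beta = beta * 2 if beta_hi == np.inf else (beta + beta_hi) / 2
            else:
                beta_hi = beta
                beta = (beta_lo + beta) / 2
        w = np.exp(-beta * di)
        pr = w / w.sum()
        p_b = np.array([pr[ci == b].sum() for b in range(n_batches)])
        scores[i] = 1.0 / (p_b ** 2).sum()
    return scores


@dataclass
class DendrogramResult:
    linkage: np.ndarray
    purity: dict[str, float]
    cut_labels: np.ndarray


def celltype_dendrogram(sim: np.ndarray, labels) -> DendrogramResult:
    """Average-linkage tree on distance ``1 - similarity`` with type purity.

    Purity of a cell type is the fraction of its cells falling in its
    majority cluster when the tree is cut into as many clusters as there are
    types.
    """
    sim = np.asarray(sim, dtype=float)
    if sim.shape[0] != sim.shape[1] or not np.allclose(sim, sim.T):
        raise ValueError("similarity matrix must be square and symmetric")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = np.asarray(labels)
    k = len(set(labels.tolist()))
    cut = hierarchy.fcluster(link, t=k, criterion="maxclust")
    purity = {}
    for lab in sorted(set(labels.tolist())):
        members = cut[labels == lab]
        counts = np.bincount(members)
        purity[str(lab)] = counts.max() / members.size
    return DendrogramResult(link, purity, cut)


# ---------------------------------------------------------------------------
# Benchmark harness


def pca_project(X: np.ndarray, n_components: int = 50,
                seed: int = 0) -> np.ndarray:
    """Project to the top principal components (capped by matrix rank)."""
    X = np.asarray(X, dtype=float)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    return PCA(n_components=n_components, random_state=seed).fit_transform(X)


def clustering_benchmark(embedding: np.ndarray, true_labels,
                         projections: dict[str, np.ndarray] | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """ARI (K-means and Louvain) plus silhouette on each coordinate space.

    ``projections`` supplies precomputed 2-D views (e.g. t-SNE/UMAP
    coordinates); together with the raw embedding these yield the standard
    clusterer x space evaluation grid.
    """
    true_labels = np.asarray(true_labels)
    k = len(set(true_labels.tolist()))
    spaces = {"embedding": np.asarray(embedding)}
    spaces.update(projections or {})
    rows = []
    for name, coords in spaces.items():
        km = kmeans_labels(coords, k, seed=seed)
        rows.append((name, "kmeans", adjusted_rand_index(true_labels, km),
                     mean_silhouette(coords, true_labels)))
        try:
            lv = louvain_target_k(coords, k, seed=seed)
            ari_lv = adjusted_rand_index(true_labels, lv)
        except ValueError:
            ari_lv = np.nan
        rows.append((name, "louvain", ari_lv,
                     mean_silhouette(coords, true_labels)))
    return pd.DataFrame(rows, columns=["space", "clusterer", "ari",
                                       "silhouette"])
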