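"""Unsupervised identification of leads and participants from heartbeats.

The pipeline is: PCA retaining a target fraction of variance (99% by
default, which lands around 10–20 components for 121-sample beats) →
restarted k-means on the reduced coordinates (the best of five restarts
by the largest sum of squared pairwise centroid distances after up to
1000 iterations) → optimal cluster-to-class assignment via the Hungarian
(Munkres) algorithm on a co-occurrence cost matrix → scoring.

Scoring follows the aggregate conventions used with this procedure:

    accuracy  = (1/N) Σ_i 1[y_i = ŷ_i]
    micro-F1  = 2A / (N + A),           A = Σ_i 1[y_i = ŷ_i]
    macro-F1  = (1/C) Σ_c 2·TP_c / (N + TP_c)

Note the macro form divides each class's true positives by the *global*
N, making F1_c a per-class micro-F1; it therefore collapses toward the
micro form rather than averaging conventional per-class F1 scores.  A
standard macro-F1 (precision/recall per class) is available behind
``standard_macro=True`` for comparison.

Centroid waveforms in the original heartbeat space are recovered by the
inverse PCA transform of the k-means centroids; t-SNE (perplexity 30,
Euclidean distance) is provided for visualization only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import f1_score

from .heartbeats import BeatMatrix


@dataclass
class EmbeddingResult:
    """PCA basis, mean and reduced coordinates of a beat batch."""

    basis: np.ndarray        # (k, n_features)
    mean: np.ndarray         # (n_features,)
    coords: np.ndarray       # (n, k)
    explained_variance_fraction: np.ndarray  # per retained component

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    def inverse_transform(self, coords: np.ndarray) -> np.ndarray:
        return np.atleast_2d(coords) @ self.basis + self.mean


@dataclass
class ClusterResult:
    """Clustering output plus (optionally) mapping and metrics."""

    centroids: np.ndarray                  # (K, k)
    cluster_labels: np.ndarray             # per sample
    true_labels: np.ndarray | None = None
    mapping: dict | None = None            # cluster -> class (-1 if unmapped)
    metrics: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.cluster_labels.size

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def mapped_labels(self) -> np.ndarray:
        if self.mapping is None:
            raise ValueError("no cluster-to-class mapping set")
        return np.asarray([self.mapping.get(c, -1) for c in self.cluster_labels],
                          dtype=object)


def pca_reduce(beats: BeatMatrix | np.ndarray,
               variance_target: float = 0.99) -> EmbeddingResult:
    """Reduce beats to the smallest PCA basis reaching the variance target."""
    X = beats.beats if isinstance(beats, BeatMatrix) else np.asarray(beats, dtype=float)
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    if X.shape[0] < 2:
        raise ValueError("need at least two beats")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate input: all beats identical (zero variance)")
    pca = PCA(n_components=None, svd_solver="full")
    coords_full = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    if not np.any(ratios > 0):
        raise ValueError("degenerate input: all beats identical (zero variance)")
    cumulative = np.cumsum(ratios)
    k = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    k = min(k, ratios.size)
    return EmbeddingResult(basis=pca.components_[:k],
                           mean=pca.mean_,
                           coords=coords_full[:, :k],
                           explained_variance_fraction=ratios[:k])


def _centroid_spread(centroids: np.ndarray) -> float:
    """Sum over unordered centroid pairs of squared Euclidean distance."""
    diff = centroids[:, None, :] - centroids[None, :, :]
    return float((diff ** 2).sum()) / 2.0


def kmeans_best(coords: np.ndarray, K: int, restarts: int = 5,
                iters: int = 1000, seed: int = 0,
                init: str = "k-means++") -> ClusterResult:
    """Best of ``restarts`` k-means runs by maximal centroid spread.

    Each restart draws its initial centroids from a seeded stream and
    runs up to ``iters`` Lloyd iterations; among the restarts, the run
    maximizing the sum of squared pairwise centroid distances is
    returned.  Initialization defaults to k-means++ seeding: with plain
    uniform choice of data points a restart that lands two seeds in one
    well-separated mode can never recover, and five restarts leave a
    non-negligible chance that none finds the true partition.
    ``init="random"`` is available for the plain variant.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    if K < 1 or restarts < 1:
        raise ValueError("K and restarts must be >= 1")
    states = np.random.SeedSequence(seed).generate_state(restarts)
    best: tuple[float, KMeans] | None = None
    for rs in states:
        km = KMeans(n_clusters=K, init=init, n_init=1, max_iter=iters,
                    random_state=int(rs % (2 ** 31))).fit(coords)
        spread = _centroid_spread(km.cluster_centers_)
        if best is None or spread > best[0]:
            best = (spread, km)
    km = best[1]
    return ClusterResult(centroids=km.cluster_centers_,
                         cluster_labels=km.labels_.copy())


def _cooccurrence(true_labels: np.ndarray, cluster_labels: np.ndarray,
                  classes: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    counts = np.zeros((clusters.size, classes.size), dtype=int)
    class_idx = {c: j for j, c in enumerate(classes)}
    cluster_idx = {k: i for i, k in enumerate(clusters)}
    for y, c in zip(true_labels, cluster_labels):
        counts[cluster_idx[c], class_idx[y]] += 1
    return counts


def munkres_map(true_labels: np.ndarray, cluster_labels: np.ndarray) -> dict:
    """Optimal cluster-to-class assignment on a co-occurrence cost matrix.

    cost[cluster, class] = −(number of samples where they co-occur); the
    assignment minimizing total cost is returned as a dict.  Ties are
    broken deterministically: among equal-cost assignments the
    lexicographically smallest in (cluster index, class index) order is
    chosen, so the lowest-indexed cluster keeps the lowest-indexed of
    its equally good classes.  With more clusters than classes the
    mapping is partial and unmapped clusters map to −1.
    """
    true_labels = np.asarray(true_labels)
    cluster_labels = np.asarray(cluster_labels)
    if true_labels.size == 0 or cluster_labels.size == 0:
        raise ValueError("labels must be nonempty")
    if true_labels.shape != cluster_labels.shape:
        raise ValueError("label arrays must have equal length")
    classes = np.unique(true_labels)
    clusters = np.unique(cluster_labels)
    counts = _cooccurrence(true_labels, cluster_labels, classes, clusters)
    cost = -counts.astype(float)

    def optimal_cost(c: np.ndarray) -> float:
        rows, cols = linear_sum_assignment(c)
        return float(c[rows, cols].sum())

    base = optimal_cost(cost)
    big = counts.sum() + 1.0
    work = cost.copy()
    fixed: dict[int, int] = {}
    # greedy lexicographic fixing: cluster i takes the smallest class j
    # that still admits a completion at the optimal total cost
    for i in range(work.shape[0]):
        if work.shape[0] > work.shape[1] and len(fixed) >= work.shape[1]:
            break
        for j in range(work.shape[1]):
            if j in fixed.values():
                continue
            trial = work.copy()
            trial[i, :] = big
            trial[:, j] = big
            trial[i, j] = cost[i, j]
            try:
                if np.isclose(optimal_cost(trial), base):
                    fixed[i] = j
                    work = trial
                    break
            except ValueError:
                continue
    mapping = {clusters[i]: classes[j] for i, j in fixed.items()}
    for k in clusters:
        mapping.setdefault(k, -1)
    return mapping


def munkres_map_bruteforce(true_labels: np.ndarray,
                           cluster_labels: np.ndarray) -> dict:
    """Exhaustive-search oracle over all injective mappings (small C only)."""
    true_labels = np.asarray(true_labels)
    cluster_labels = np.asarray(cluster_labels)
    classes = np.unique(true_labels)
    clusters = np.unique(cluster_labels)
    if max(classes.size, clusters.size) > 8:
        raise ValueError("brute force oracle limited to small label sets")
    counts = _cooccurrence(true_labels, cluster_labels, classes, clusters)
    best_perm, best_score = None, -1
    if clusters.size <= classes.size:
        for perm in permutations(range(classes.size), clusters.size):
            score = sum(counts[i, perm[i]] for i in range(clusters.size))
            if score > best_score:
                best_score, best_perm = score, perm
        return {clusters[i]: classes[best_perm[i]] for i in range(clusters.size)}
    for perm in permutations(range(clusters.size), classes.size):
        score = sum(counts[perm[j], j] for j in range(classes.size))
        if score > best_score:
            best_score, best_perm = score, perm
    mapping = {clusters[perm_i]: classes[j] for j, perm_i in enumerate(best_perm)}
    for k in clusters:
        mapping.setdefault(k, -1)
    return mapping


def clustering_metrics(true_labels: np.ndarray,
                       predicted_labels: np.ndarray,
                       standard_macro: bool = False) -> dict:
    """Accuracy, micro-F1 and macro-F1 under the aggregate conventions above.

    ``predicted_labels`` are cluster labels already mapped to classes.
    With ``standard_macro=True`` the conventional per-class
    precision/recall macro-F1 is added under ``macro_f1_standard``.
    """
    y = np.asarray(true_labels)
    yhat = np.asarray(predicted_labels)
    n = y.size
    if n == 0:
        raise ValueError("cannot score an empty label set")
    if y.shape != yhat.shape:
        raise ValueError("label arrays must have equal length")
    agree = int((y == yhat).sum())
    accuracy = agree / n
    micro_f1 = 2.0 * agree / (n + agree)
    classes = np.unique(y)
    tp = np.array([int(((y == c) & (yhat == c)).sum()) for c in classes])
    macro_f1 = float(np.mean(2.0 * tp / (n + tp)))
    out = {"accuracy": accuracy, "micro_f1": micro_f1, "macro_f1": macro_f1,
           "n": n, "n_correct": agree,
           "per_class_tp": {c: int(t) for c, t in zip(classes, tp)}}
    if standard_macro:
        out["macro_f1_standard"] = float(
            f1_score(y.astype(str), yhat.astype(str), average="macro"))
    return out


def score_clusters(result: ClusterResult, true_labels: np.ndarray,
                   standard_macro: bool = False) -> ClusterResult:
    """Map clusters to classes and attach metrics to the result in place."""
    result.true_labels = np.asarray(true_labels)
    result.mapping = munkres_map(result.true_labels, result.cluster_labels)
    result.metrics = clustering_metrics(result.true_labels,
                                        result.mapped_labels(),
                                        standard_macro=standard_macro)
    return result


def centroid_heartbeats(result: ClusterResult, emb: EmbeddingResult) -> np.ndarray:
    """Inverse-PCA transform of the k-means centroids back to beat space."""
    if result.centroids.shape[1] != emb.n_components:
        raise ValueError("centroid dimensionality does not match the embedding")
    return emb.inverse_transform(result.centroids)


def tsne_project(coords: np.ndarray, perplexity: float = 30.0,
                 seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding for visualization (deterministic per seed)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= 3 * perplexity:
        raise ValueError("need n > 3 x perplexity samples for t-SNE")
    tsne = TSNE(n_components=2, perplexity=perplexity, metric="euclidean",
                init="pca", random_state=seed)
    return tsne.fit_transform(coords)
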