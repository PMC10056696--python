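"""Chunked k-means clustering with a count-weighted centroid merge.

The dataset is split into chunks after a seeded shuffle. Each round, every
worker assigns its chunk to the current *global* centroids and reports
per-cluster intensity sums and counts; the coordinator pools them and divides,
which is the numerically exact form of count-weighted averaging of the
workers' local centroids. The round loop stops when the maximum Euclidean
centroid displacement falls below ``shift_threshold`` or after ``max_rounds``.

Workers are pure functions of (chunk, global centroids): the result depends
only on the data and configuration, never on scheduling or the degree of
concurrency. With ``n_chunks=1`` the procedure is bit-identical to sequential
Lloyd iteration (chunk indices are sorted within each chunk, so a single
chunk visits rows in their original order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin


@dataclass
class KMeansConfig:
    """Configuration for chunked k-means.

    k : number of clusters (>= 1)
    max_rounds : cap on coordinator rounds (>= 1)
    shift_threshold : stop when the max centroid displacement drops below
        this value (feature units, >= 0)
    n_chunks : number of worker chunks (>= 1)
    seed : seed for centroid sampling and the chunk shuffle
    """

    k: int = 8
    max_rounds: int = 100
    shift_threshold: float = 1e-6
    n_chunks: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.max_rounds < 1:
            raise ValueError(f"max_rounds must be >= 1, got {self.max_rounds}")
        if self.shift_threshold < 0:
            raise ValueError("shift_threshold must be >= 0")
        if self.n_chunks < 1:
            raise ValueError(f"n_chunks must be >= 1, got {self.n_chunks}")


@dataclass
class ClusterModel:
    """Fitted k-means state: centroids, cluster sizes and inertia (WCSS)."""

    centroids: np.ndarray            # (k, d)
    counts: np.ndarray               # (k,) point counts, summing to n
    inertia: float                   # within-cluster sum of squared distances
    rounds_run: int
    inertia_history: list[float] = field(default_factory=list)
    config: KMeansConfig | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_dict(self) -> dict:
        return {
            "centroids": self.centroids.tolist(),
            "counts": self.counts.tolist(),
            "inertia": float(self.inertia),
            "rounds_run": int(self.rounds_run),
            "config": None if self.config is None else vars(self.config),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        cfg = KMeansConfig(**d["config"]) if d.get("config") else None
        return cls(
            centroids=np.asarray(d["centroids"], dtype=float),
            counts=np.asarray(d["counts"], dtype=np.int64),
            inertia=float(d["inertia"]),
            rounds_run=int(d["rounds_run"]),
            config=cfg,
        )


def _as_matrix(data) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2:
        raise ValueError(f"data must be a 2-D matrix, got ndim={X.ndim}")
    if X.size == 0:
        raise ValueError("data must be non-empty")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains non-finite values")
    return X


def init_centroids(data, config: KMeansConfig) -> np.ndarray:
    """Sample ``k`` distinct rows of *data* without replacement under the seed."""
    X = _as_matrix(data)
    n = X.shape[0]
    if n < config.k:
        raise ValueError(f"need at least k={config.k} points, got {n}")
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(n, size=config.k, replace=False)
    return X[idx].copy()


def assign_points(data, centroids) -> np.ndarray:
    """Label each point with its nearest centroid (Euclidean, ties -> lowest index)."""
    X = _as_matrix(data)
    C = np.asarray(centroids, dtype=float)
    if C.ndim != 2 or C.shape[1] != X.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has d={X.shape[1]}, centroids {C.shape}"
        )
    d2 = cdist(X, C, metric="sqeuclidean")
    return np.argmin(d2, axis=1)   # argmin takes the lowest index on ties


def update_centroids(data, labels, k: int,
                     prev_centroids: np.ndarray | None = None) -> np.ndarray:
    """Per-cluster means. An empty cluster is re-seeded to the point farthest
    from its previous centroid; when ``prev_centroids`` is not supplied the
    global data mean stands in as the reference point."""
    X = _as_matrix(data)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("labels must lie in 0..k-1")
    out = np.empty((k, X.shape[1]), dtype=float)
    empty = []
    for j in range(k):
        mask = labels == j
        cnt = int(mask.sum())
        if cnt == 0:
            empty.append(j)
            out[j] = np.nan
        else:
            out[j] = X[mask].sum(axis=0) / cnt
    if empty:
        if prev_centroids is not None:
            _reseed_empty(X, out, np.asarray(prev_centroids, dtype=float), empty)
        else:
            ref = X.mean(axis=0)
            for j in empty:
                far = np.argmax(((X - ref) ** 2).sum(axis=1))
                out[j] = X[far]
    return out


def _reseed_empty(X: np.ndarray, centroids: np.ndarray, prev: np.ndarray,
                  empty: list[int]) -> None:
    """Re-seed empty clusters in-place to the point farthest from the
    cluster's previous centroid."""
    for j in empty:
        far = np.argmax(((X - prev[j]) ** 2).sum(axis=1))
        centroids[j] = X[far]


def _chunk_indices(n: int, n_chunks: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, contiguous blocks, indices sorted within each block.

    Sorting restores original row order inside a chunk (stable summation
    order; a single chunk then coincides with plain sequential iteration).
    """
    rng = np.random.default_rng([seed, 1])
    perm = rng.permutation(n)
    return [np.sort(p) for p in np.array_split(perm, n_chunks)]


def _worker_step(block: np.ndarray, centroids: np.ndarray, k: int):
    """Pure worker: assign a block to the global centroids, return
    per-cluster (sum, count) and the block's SSE contribution."""
    labels = assign_points(block, centroids)
    d = block.shape[1]
    sums = np.zeros((k, d))
    counts = np.zeros(k, dtype=np.int64)
    for j in range(k):
        mask = labels == j
        c = int(mask.sum())
        counts[j] = c
        if c:
            sums[j] = block[mask].sum(axis=0)
    sse = float(((block - centroids[labels]) ** 2).sum())
    return sums, counts, sse


def fit_parallel(data, config: KMeansConfig,
                 init: np.ndarray | None = None) -> ClusterModel:
    """Run chunked k-means to convergence.

    ``init`` optionally overrides the seeded row-sampling initialization
    (used e.g. by the image pipeline, which seeds from distinct intensity
    values).
    """
    X = _as_matrix(data)
    n, _ = X.shape
    k = config.k
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if init is None:
        centroids = init_centroids(X, config)
    else:
        centroids = np.asarray(init, dtype=float).copy()
        if centroids.shape != (k, X.shape[1]):
            raise ValueError("init centroids have wrong shape")

    chunks = _chunk_indices(n, config.n_chunks, config.seed)
    blocks = [X[idx] for idx in chunks]

    history: list[float] = []
    rounds = 0
    for _ in range(config.max_rounds):
        total_sums = np.zeros_like(centroids)
        total_counts = np.zeros(k, dtype=np.int64)
        sse = 0.0
        # workers are independent; sequential emulation is the reference
        for block in blocks:
            s, c, e = _worker_step(block, centroids, k)
            total_sums += s
            total_counts += c
            sse += e
        history.append(sse)
        new = np.empty_like(centroids)
        empty = []
        for j in range(k):
            if total_counts[j] > 0:
                new[j] = total_sums[j] / total_counts[j]
            else:
                empty.append(j)
                new[j] = centroids[j]
        if empty:
            _reseed_empty(X, new, centroids, empty)
        shift = float(np.sqrt(((new - centroids) ** 2).sum(axis=1)).max())
        centroids = new
        rounds += 1
        if shift < config.shift_threshold:
            break

    labels = assign_points(X, centroids)
    counts = np.bincount(labels, minlength=k).astype(np.int64)
    inertia = float(((X - centroids[labels]) ** 2).sum())
    return ClusterModel(centroids=centroids, counts=counts, inertia=inertia,
                        rounds_run=rounds, inertia_history=history,
                        config=config)


def predict(model: ClusterModel, points) -> np.ndarray:
    """Assign new points to the fitted centroids (same rule as training)."""
    return assign_points(points, model.centroids)


class ParallelKMeans(ClusterMixin, BaseEstimator):
    """Chunked k-means estimator.

    Parameters
    ----------
    n_clusters : int, default=8
    n_chunks : int, default=1
        Number of worker chunks; the result is independent of this choice's
        scheduling (identical reruns), though the fitted centroids depend on
        the chunking itself.
    max_rounds : int, default=100
    shift_threshold : float, default=1e-6
        Convergence threshold on the maximum centroid displacement.
    random_state : int, default=0

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    labels_ : ndarray of shape (n_samples,)
    counts_ : ndarray of shape (n_clusters,)
    inertia_ : float
    n_rounds_ : int
    inertia_history_ : list of float, per-round SSE against the round's
        starting centroids.
    """

    def __init__(self, n_clusters=8, n_chunks=1, max_rounds=100,
                 shift_threshold=1e-6, random_state=0):
        self.n_clusters = n_clusters
        self.n_chunks = n_chunks
        self.max_rounds = max_rounds
        self.shift_threshold = shift_threshold
        self.random_state = random_state

    def _config(self) -> KMeansConfig:
        return KMeansConfig(k=self.n_clusters, max_rounds=self.max_rounds,
                            shift_threshold=self.shift_threshold,
                            n_chunks=self.n_chunks, seed=self.random_state)

    def fit(self, X, y=None):
        model = fit_parallel(X, self._config())
        self.model_ = model
        self.cluster_centers_ = model.centroids
        self.counts_ = model.counts
        self.inertia_ = model.inertia
        self.n_rounds_ = model.rounds_run
        self.inertia_history_ = model.inertia_history
        self.labels_ = assign_points(_as_matrix(X), model.centroids)
        return self

    def predict(self, X):
        if not hasattr(self, "cluster_centers_"):
            raise ValueError("ParallelKMeans instance is not fitted yet")
        return assign_points(X, self.cluster_centers_)

    def transform(self, X):
        """Distances to each fitted centroid."""
        if not hasattr(self, "cluster_centers_"):
            raise ValueError("ParallelKMeans instance is not fitted yet")
        return cdist(_as_matrix(X), self.cluster_centers_)
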