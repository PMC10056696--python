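import numpy as np
import pytest
from scipy.spatial.distance import cdist


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def lloyd_oracle(X, k, seed, max_rounds=100, shift_threshold=1e-6):
    """Independent textbook Lloyd implementation (test oracle).

    Seeded row-sampling init, assign/update rounds, stop when the max
    centroid displacement drops below the threshold; empty clusters are
    re-seeded to the point farthest from their previous centroid.
    Returns (centroids, labels, inertia, rounds).
    """
    X = np.asarray(X, dtype=float)
    g = np.random.default_rng(seed)
    C = X[g.choice(len(X), size=k, replace=False)].copy()
    rounds = 0
    for _ in range(max_rounds):
        labels = np.argmin(cdist(X, C, "sqeuclidean"), axis=1)
        new = np.empty_like(C)
        for j in range(k):
            m = labels == j
            if m.sum():
                new[j] = X[m].mean(axis=0)
            else:
                new[j] = X[np.argmax(((X - C[j]) ** 2).sum(axis=1))]
        shift = np.sqrt(((new - C) ** 2).sum(axis=1)).max()
        C = new
        rounds += 1
        if shift < shift_threshold:
            break
    labels = np.argmin(cdist(X, C, "sqeuclidean"), axis=1)
    inertia = float(((X - C[labels]) ** 2).sum())
    return C, labels, inertia, rounds


@pytest.fixture
def three_blob_data():
    """Well-separated 3-component Gaussian mixture, n=600, seed 1."""
    g = np.random.default_rng(1)
    means = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
    return np.vstack([g.normal(size=(200, 2)) + mu for mu in means])
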