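"""Cluster-driven tabular preprocessing.

Four effects of running k-means ahead of the classifier, plus mean
imputation: (1) mean imputation of missing cells, (2) min-max scaling to
[0, 1], (3) outlier flagging by distance to the assigned centroid, and
(4) cluster-feature augmentation (one-hot membership indicators and/or the
distance-to-centroid embedding that serves as a k-dimensional reduction).

Pipeline order is impute -> normalize -> cluster -> flag -> augment:
clustering needs complete, comparably scaled features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .kmeans import ClusterModel, assign_points


@dataclass
class TabularDataset:
    """Feature matrix with optional binary labels; NaN marks a missing cell."""

    features: np.ndarray                      # (n, d) float, NaN = missing
    labels: np.ndarray | None = None          # (n,) in {0, 1}
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.features.shape[0]:
                raise ValueError("labels length must match features rows")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0/1")
        if not self.feature_names:
            self.feature_names = [f"x{i}" for i in range(self.features.shape[1])]
        elif len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match feature count")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def replace(self, features, feature_names=None) -> "TabularDataset":
        return TabularDataset(
            features=features,
            labels=None if self.labels is None else self.labels.copy(),
            feature_names=list(feature_names or self.feature_names),
        )


class MeanImputer(TransformerMixin, BaseEstimator):
    """Replace NaN cells by the column mean over observed cells.

    Attributes
    ----------
    means_ : ndarray of shape (n_features,), observed-cell column means.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        observed = ~np.isnan(X)
        if not observed.any(axis=0).all():
            bad = np.where(~observed.any(axis=0))[0]
            raise ValueError(f"column(s) {bad.tolist()} are fully missing")
        self.means_ = np.nanmean(X, axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).copy()
        missing = np.isnan(X)
        X[missing] = np.broadcast_to(self.means_, X.shape)[missing]
        return X


class MinMaxNormalizer(TransformerMixin, BaseEstimator):
    """Scale each feature to [0, 1] via (x - min) / (max - min).

    Constant features map to 0. Fitted ``min_``/``max_`` are the record to
    apply to new data. Refuses missing values: impute first.
    """

    def fit(self, X, y=None):
        X = self._check(X)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        return self

    def transform(self, X):
        X = self._check(X)
        span = self.max_ - self.min_
        out = np.zeros_like(X)
        nz = span != 0
        out[:, nz] = (X[:, nz] - self.min_[nz]) / span[nz]
        return out

    @staticmethod
    def _check(X):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing values present; run imputation first")
        return X


def impute_mean(ds: TabularDataset) -> TabularDataset:
    """Mean-impute missing cells of a dataset (observed cells untouched)."""
    return ds.replace(MeanImputer().fit_transform(ds.features))


def minmax_normalize(ds: TabularDataset):
    """Normalize features to [0, 1]; returns (dataset, fitted normalizer)."""
    norm = MinMaxNormalizer().fit(ds.features)
    return ds.replace(norm.transform(ds.features)), norm


def flag_outliers(ds: TabularDataset, model: ClusterModel,
                  q: float = 0.99) -> np.ndarray:
    """Flag rows whose distance to their assigned centroid exceeds the
    q-quantile of all such distances. Returns a boolean mask."""
    if not (0 < q < 1):
        raise ValueError(f"q must be in (0, 1), got {q}")
    labels = assign_points(ds.features, model.centroids)
    dists = np.sqrt(((ds.features - model.centroids[labels]) ** 2).sum(axis=1))
    return dists > np.quantile(dists, q)


def augment_cluster_features(ds: TabularDataset, model: ClusterModel,
                             mode: str = "indicators") -> TabularDataset:
    """Add cluster-derived features.

    mode='indicators' appends k one-hot cluster-membership columns;
    mode='centroids' replaces the features with the k distances to the
    centroids (the dimensionality-reduction embedding);
    mode='both' appends both the distances and the indicators.
    """
    if mode not in ("indicators", "centroids", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = assign_points(ds.features, model.centroids)
    k = model.k
    onehot = np.eye(k)[labels]
    dists = np.sqrt(
        ((ds.features[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    )
    ind_names = [f"cluster_{j}" for j in range(k)]
    dist_names = [f"dist_c{j}" for j in range(k)]
    if mode == "indicators":
        feats = np.hstack([ds.features, onehot])
        names = ds.feature_names + ind_names
    elif mode == "centroids":
        feats = dists
        names = dist_names
    else:
        feats = np.hstack([ds.features, dists, onehot])
        names = ds.feature_names + dist_names + ind_names
    return ds.replace(feats, feature_names=names)


def drop_rows(ds: TabularDataset, mask: np.ndarray) -> TabularDataset:
    """Remove rows where *mask* is True (e.g. flagged outliers)."""
    keep = ~np.asarray(mask, dtype=bool)
    return TabularDataset(
        features=ds.features[keep],
        labels=None if ds.labels is None else ds.labels[keep],
        feature_names=list(ds.feature_names),
    )
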