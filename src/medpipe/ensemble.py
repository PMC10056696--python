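"""Weighted ensemble of chunk-trained logistic models.

The training set is partitioned into chunks; one logistic model is fitted
per chunk (each fit is a pure function of its chunk, the hyperparameters and
a derived seed, so the degree of concurrency never changes the result). Each
member receives a weight proportional to its validation metric (accuracy or
ROC AUC), normalized to sum to 1; the combined prediction is the convex
mixture p(x) = sum_i w_i p_i(x). Weights are then refined by a coordinate-
wise multiplicative search (x1.1 / x0.9, renormalize, keep on improvement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._seeds import derive_seed
from .logistic import LogRegModel, fit_gd, predict_proba
from .metrics import accuracy_score, auc_roc, report_dict
from .preprocess import (TabularDataset, augment_cluster_features, drop_rows,
                         flag_outliers, impute_mean, minmax_normalize)
from .kmeans import KMeansConfig, fit_parallel


@dataclass
class SplitSpec:
    """Train/validation/test split specification (70/30 by default, the
    validation set carved from the training fraction)."""

    train_fraction: float = 0.70
    test_fraction: float = 0.30
    val_fraction_of_train: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1 and 0 < self.test_fraction < 1):
            raise ValueError("fractions must be in (0, 1)")
        if abs(self.train_fraction + self.test_fraction - 1) > 1e-9:
            raise ValueError("train and test fractions must sum to 1")
        if not (0 <= self.val_fraction_of_train < 1):
            raise ValueError("val_fraction_of_train must be in [0, 1)")


@dataclass
class EnsembleModel:
    """Members M1..Mn with normalized non-negative weights summing to 1."""

    members: list[LogRegModel]
    weights: np.ndarray
    weight_metric: str = "accuracy"
    refinement_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != self.weights.shape[0]:
            raise ValueError("weights/member count mismatch")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def to_dict(self) -> dict:
        return {
            "members": [m.to_dict() for m in self.members],
            "weights": self.weights.tolist(),
            "weight_metric": self.weight_metric,
            "refinement_log": list(self.refinement_log),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            members=[LogRegModel.from_dict(m) for m in d["members"]],
            weights=np.asarray(d["weights"], dtype=float),
            weight_metric=d.get("weight_metric", "accuracy"),
            refinement_log=list(d.get("refinement_log", [])),
        )


def split_data(X, y, spec: SplitSpec):
    """Seeded (optionally stratified) partition into train/val/test index
    arrays at the specified fractions; disjoint and covering."""
    X = np.asarray(X)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(spec.seed)
    n_test = round(spec.test_fraction * n)

    if spec.stratified:
        test_parts, train_parts = [], []
        for cls in np.unique(y):
            idx = rng.permutation(np.where(y == cls)[0])
            t = round(spec.test_fraction * idx.size)
            test_parts.append(idx[:t])
            train_parts.append(idx[t:])
        test_idx = np.sort(np.concatenate(test_parts))
        trainval_idx = rng.permutation(np.concatenate(train_parts))
        if np.unique(y[trainval_idx]).size < np.unique(y).size:
            raise ValueError("a class is absent from the training split")
    else:
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        trainval_idx = perm[n_test:]

    n_val = round(spec.val_fraction_of_train * trainval_idx.size)
    val_idx = np.sort(trainval_idx[:n_val])
    train_idx = np.sort(trainval_idx[n_val:])
    return train_idx, val_idx, test_idx


def partition_chunks(n_rows: int, n_chunks: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle then contiguous blocks with sizes differing by <= 1."""
    if n_chunks > n_rows:
        raise ValueError(f"n_chunks={n_chunks} exceeds rows={n_rows}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    return [np.sort(p) for p in np.array_split(perm, n_chunks)]


def _member_scores(members, X_val, y_val, metric: str) -> np.ndarray:
    if metric == "accuracy":
        return np.array([
            accuracy_score(y_val, (predict_proba(m, X_val) >= 0.5).astype(int))
            for m in members
        ])
    if metric == "auc":
        if np.unique(y_val).size < 2:
            raise ValueError("AUC weighting needs both classes in validation")
        return np.array([auc_roc(predict_proba(m, X_val), y_val)
                         for m in members])
    raise ValueError(f"unknown metric {metric!r}")


def compute_weights(members, X_val, y_val,
                    metric: str = "accuracy") -> np.ndarray:
    """Weights proportional to each member's validation metric (sum to 1);
    all-zero metrics fall back to uniform weights."""
    if len(np.asarray(y_val)) == 0:
        raise ValueError("validation set is empty")
    scores = _member_scores(members, X_val, y_val, metric)
    total = scores.sum()
    if total == 0:
        return np.full(len(members), 1.0 / len(members))
    return scores / total


def combine_probabilities(prob_matrix, weights) -> np.ndarray:
    """Weighted sum of member probabilities: p = sum_i w_i p_i."""
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))  # (members, n)
    w = np.asarray(weights, dtype=float)
    if P.shape[0] != w.shape[0]:
        raise ValueError("weight/member count mismatch")
    return w @ P


def combine_predict(ens: EnsembleModel, X) -> np.ndarray:
    """Combined positive-class probabilities of the ensemble."""
    P = np.vstack([predict_proba(m, X) for m in ens.members])
    return combine_probabilities(P, ens.weights)


def _ensemble_score(ens: EnsembleModel, X_val, y_val, metric: str) -> float:
    p = combine_predict(ens, X_val)
    if metric == "accuracy":
        return accuracy_score(y_val, (p >= 0.5).astype(int))
    return auc_roc(p, y_val)


def refine_weights(ens: EnsembleModel, X_val, y_val,
                   max_rounds: int = 20) -> EnsembleModel:
    """Coordinate-wise multiplicative weight search.

    Each round tries scaling every weight by 1.1 and 0.9 (renormalized) and
    accepts the best strictly-improving candidate; stops on a round with no
    improvement or after ``max_rounds``. Accepted validation scores are
    appended to ``refinement_log`` (which starts with the initial score).
    """
    metric = ens.weight_metric
    w = ens.weights.copy()
    score = _ensemble_score(ens, X_val, y_val, metric)
    log = [score]
    for _ in range(max_rounds):
        best_w, best_score = None, score
        for i in range(w.size):
            for factor in (1.1, 0.9):
                cand = w.copy()
                cand[i] *= factor
                cand /= cand.sum()
                c_ens = EnsembleModel(members=ens.members, weights=cand,
                                      weight_metric=metric)
                s = _ensemble_score(c_ens, X_val, y_val, metric)
                if s > best_score:
                    best_w, best_score = cand, s
        if best_w is None:
            break
        w, score = best_w, best_score
        log.append(score)
    return EnsembleModel(members=ens.members, weights=w, weight_metric=metric,
                         refinement_log=list(ens.refinement_log) + log)


class ChunkedLogisticEnsemble(ClassifierMixin, BaseEstimator):
    """Ensemble of logistic models trained on data chunks.

    ``fit(X, y)`` carves a validation subset from the supplied training data
    (``val_fraction``), partitions the remainder into ``n_chunks``, fits one
    :func:`medpipe.logistic.fit_gd` model per chunk under a per-member derived
    seed, computes validation-proportional weights and refines them.

    Attributes
    ----------
    members_ : list of LogRegModel
    weights_ : ndarray summing to 1
    chunk_indices_ : list of ndarray, row indices of each member's chunk
        (relative to the supplied X)
    refinement_log_ : accepted validation scores
    """

    def __init__(self, n_chunks=1, alpha=1.0, max_iters=20000, tol=1e-9,
                 weight_metric="accuracy", refine_rounds=20,
                 val_fraction=0.2, random_state=0):
        self.n_chunks = n_chunks
        self.alpha = alpha
        self.max_iters = max_iters
        self.tol = tol
        self.weight_metric = weight_metric
        self.refine_rounds = refine_rounds
        self.val_fraction = val_fraction
        self.random_state = random_state

    def member_seed(self, i: int) -> int:
        return derive_seed(self.random_state, f"member{i}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n = X.shape[0]
        rng = np.random.default_rng(derive_seed(self.random_state, "valsplit"))
        perm = rng.permutation(n)
        n_val = round(self.val_fraction * n)
        val_idx = np.sort(perm[:n_val])
        fit_idx = np.sort(perm[n_val:])

        chunks_rel = partition_chunks(fit_idx.size, self.n_chunks,
                                      derive_seed(self.random_state, "chunks"))
        self.chunk_indices_ = [fit_idx[c] for c in chunks_rel]
        self.val_indices_ = val_idx

        members = [
            fit_gd(X[idx], y[idx], alpha=self.alpha, max_iters=self.max_iters,
                   tol=self.tol, seed=self.member_seed(i))
            for i, idx in enumerate(self.chunk_indices_)
        ]
        if n_val > 0 and len(members) > 1:
            w = compute_weights(members, X[val_idx], y[val_idx],
                                self.weight_metric)
        else:
            w = np.full(len(members), 1.0 / len(members))
        ens = EnsembleModel(members=members, weights=w,
                            weight_metric=self.weight_metric)
        if n_val > 0 and self.refine_rounds > 0 and len(members) > 1:
            ens = refine_weights(ens, X[val_idx], y[val_idx],
                                 max_rounds=self.refine_rounds)
        self.ensemble_ = ens
        self.members_ = ens.members
        self.weights_ = ens.weights
        self.refinement_log_ = ens.refinement_log
        self.member_val_scores_ = (
            _member_scores(members, X[val_idx], y[val_idx], self.weight_metric)
            if n_val > 0 else None
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p1 = combine_predict(self.ensemble_, X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X, thr: float = 0.5):
        return (combine_predict(self.ensemble_, X) >= thr).astype(int)


def fit_parallel_logreg(ds: TabularDataset, n_chunks: int,
                        seed: int = 0,
                        cluster_k: int = 2,
                        outlier_q: float = 0.99,
                        drop_outliers: bool = True,
                        augment_mode: str = "indicators",
                        weight_metric: str = "accuracy",
                        alpha: float = 1.0,
                        max_iters: int = 20000,
                        tol: float = 1e-9,
                        refine_rounds: int = 20):
    """End-to-end chunk-parallel logistic classification.

    Preprocess (impute -> normalize -> k-means -> outlier flag -> cluster
    features) -> 70/30 split -> chunked member fits -> validation weighting
    and refinement -> test evaluation. Returns (estimator, report dict).
    """
    if ds.labels is None:
        raise ValueError("dataset must carry binary labels")
    ds = impute_mean(ds)
    ds, _norm = minmax_normalize(ds)
    km = fit_parallel(ds.features,
                      KMeansConfig(k=cluster_k, n_chunks=n_chunks,
                                   seed=derive_seed(seed, "cluster")))
    mask = flag_outliers(ds, km, q=outlier_q)
    if drop_outliers:
        ds = drop_rows(ds, mask)
    ds = augment_cluster_features(ds, km, mode=augment_mode)

    spec = SplitSpec(seed=derive_seed(seed, "split"),
                     val_fraction_of_train=0.0)
    train_idx, _, test_idx = split_data(ds.features, ds.labels, spec)
    X_tr, y_tr = ds.features[train_idx], ds.labels[train_idx]
    X_te, y_te = ds.features[test_idx], ds.labels[test_idx]

    est = ChunkedLogisticEnsemble(
        n_chunks=n_chunks, alpha=alpha, max_iters=max_iters, tol=tol,
        weight_metric=weight_metric, refine_rounds=refine_rounds,
        random_state=derive_seed(seed, "ensemble"),
    ).fit(X_tr, y_tr)

    p_te = combine_predict(est.ensemble_, X_te)
    report = {
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
        "n_outliers_flagged": int(mask.sum()),
        "weights": est.weights_.tolist(),
        "member_val_scores": (None if est.member_val_scores_ is None
                              else np.asarray(est.member_val_scores_).tolist()),
        "refinement_log": list(est.refinement_log_),
        "test": report_dict(y_te, (p_te >= 0.5).astype(int), scores=p_te),
    }
    return est, report
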