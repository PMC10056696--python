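"""Binary logistic regression fitted by full-batch gradient ascent.

The model is p(y=1 | x) = f(w0 + w·x) with the logistic function
f(z) = 1 / (1 + e^-z). Fitting maximizes the Bernoulli log-likelihood

    l(w) = sum_i  y_i log f(z_i) + (1 - y_i) log(1 - f(z_i))

whose gradient component j is sum_i (y_i - f(z_i)) x_ij (x_i0 = 1 for the
bias). The update applies the learning rate to the *mean* gradient so the
step size is independent of sample size; iteration stops when the absolute
change of the log-likelihood drops below ``tol`` or ``max_iters`` is reached.
Weights start at small seeded uniform values in [-0.01, 0.01].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

_EPS = 1e-12


def sigmoid(z):
    """Numerically stable logistic function, elementwise."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class LogRegModel:
    """Fitted logistic model: bias w0, weights w1..wd and fit metadata."""

    bias: float
    weights: np.ndarray
    alpha: float = 0.1
    max_iters: int = 1000
    tol: float = 1e-8
    n_iters: int = 0
    final_log_likelihood: float = float("nan")
    ll_history: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "bias": float(self.bias),
            "weights": np.asarray(self.weights).tolist(),
            "alpha": self.alpha,
            "max_iters": self.max_iters,
            "tol": self.tol,
            "n_iters": self.n_iters,
            "final_log_likelihood": self.final_log_likelihood,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogRegModel":
        d = dict(d)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        d.pop("ll_history", None)
        return cls(**d)


def _check_Xy(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if y is None:
        return X, None
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be in {0, 1}")
    return X, y.astype(float)


def log_likelihood(model: LogRegModel, X, y) -> float:
    """Bernoulli log-likelihood with probabilities clipped to [eps, 1-eps]."""
    X, y = _check_Xy(X, y)
    p = np.clip(sigmoid(model.bias + X @ model.weights), _EPS, 1 - _EPS)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def gradient(model: LogRegModel, X, y) -> np.ndarray:
    """Gradient of the log-likelihood: [(y-p).sum(), X^T (y-p)]."""
    X, y = _check_Xy(X, y)
    p = sigmoid(model.bias + X @ model.weights)
    r = y - p
    return np.concatenate([[r.sum()], X.T @ r])


def fit_gd(X, y, alpha: float = 0.1, max_iters: int = 1000,
           tol: float = 1e-8, seed: int = 0) -> LogRegModel:
    """Fit by full-batch gradient ascent on the log-likelihood."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    X, y = _check_Xy(X, y)
    n, d = X.shape
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    w = rng.uniform(-0.01, 0.01, size=d + 1)
    model = LogRegModel(bias=w[0], weights=w[1:], alpha=alpha,
                        max_iters=max_iters, tol=tol)
    ll_prev = log_likelihood(model, X, y)
    model.ll_history.append(ll_prev)
    for it in range(1, max_iters + 1):
        g = gradient(model, X, y)
        w = w + alpha * g / n
        model.bias = w[0]
        model.weights = w[1:]
        ll = log_likelihood(model, X, y)
        model.ll_history.append(ll)
        model.n_iters = it
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    model.final_log_likelihood = model.ll_history[-1]
    return model


def predict_proba(model: LogRegModel, X) -> np.ndarray:
    """Positive-class probabilities f(w0 + X w)."""
    X, _ = _check_Xy(X)
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError("dimension mismatch between X and model weights")
    return sigmoid(model.bias + X @ model.weights)


def predict(model: LogRegModel, X, thr: float = 0.5) -> np.ndarray:
    """Labels at the given probability threshold."""
    return (predict_proba(model, X) >= thr).astype(int)


class LogisticRegressionGD(ClassifierMixin, BaseEstimator):
    """Gradient-ascent logistic regression classifier.

    Parameters
    ----------
    alpha : float, default=0.1
        Learning rate, applied to the mean gradient. The default assumes
        features normalized to [0, 1] or standardized.
    max_iters : int, default=1000
    tol : float, default=1e-8
        Convergence tolerance on the absolute log-likelihood change.
    random_state : int, default=0

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
    n_iter_ : int
    log_likelihood_ : float
    classes_ : ndarray [0, 1]
    """

    def __init__(self, alpha=0.1, max_iters=1000, tol=1e-8, random_state=0):
        self.alpha = alpha
        self.max_iters = max_iters
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        model = fit_gd(X, y, alpha=self.alpha, max_iters=self.max_iters,
                       tol=self.tol, seed=self.random_state)
        self.model_ = model
        self.intercept_ = model.bias
        self.coef_ = model.weights
        self.n_iter_ = model.n_iters
        self.log_likelihood_ = model.final_log_likelihood
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p1 = predict_proba(self.model_, X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X, thr: float = 0.5):
        return (predict_proba(self.model_, X) >= thr).astype(int)
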