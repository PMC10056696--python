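"""Seeded synthetic data generators.

Two generators emulate the statistical structure the pipeline assumes, so
every stage is testable without external downloads:

* :func:`gen_tabular` — a Gaussian mixture of ``k_true`` components whose
  binary labels follow a logistic mechanism y ~ Bernoulli(f(w0 + w.x));
  missing cells (NaN) and far-field outlier rows are injected afterwards, so
  the labels stay purely logistic in the clean features (which is what makes
  parameter recovery a valid check).

* :func:`gen_images` — grayscale images built from ``n_bands`` horizontal
  intensity bands plus Gaussian noise; with probability ``lesion_rate`` an
  image receives 1-3 bright elliptical lesions, each with a recorded
  ground-truth bounding box. Lesions are brighter than every band so they
  always form their own intensity cluster.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logistic import sigmoid
from .preprocess import TabularDataset

# default logistic weights, cycled to the requested dimension
_DEFAULT_W = np.array([2.0, -3.0, 1.5, -1.0, 0.5])


@dataclass
class TabularTruth:
    """Ground truth of a tabular draw: component assignments, logistic
    parameters, and the injected corruption."""

    cluster_assignments: np.ndarray
    w0: float
    w: np.ndarray
    missing_mask: np.ndarray
    outlier_indices: np.ndarray


@dataclass
class ImageTruth:
    """Per-image lesion boxes (absolute pixel corners x1, y1, x2, y2) and
    the binary affected label (affected iff >= 1 lesion)."""

    boxes: list[tuple[float, float, float, float]]
    affected: bool
    band_levels: np.ndarray


def gen_tabular(n: int = 2000, d: int = 5, k_true: int = 2,
                separation: float = 2.0, w0: float = -1.0, w=None,
                missing_rate: float = 0.05, outlier_rate: float = 0.01,
                seed: int = 0):
    """Draw a labelled Gaussian-mixture dataset with a logistic label law.

    Components have unit variance and means spaced ``separation`` standard
    deviations apart along a random unit direction. Returns
    (TabularDataset, TabularTruth).
    """
    if not (0 <= missing_rate < 1 and 0 <= outlier_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    rng = np.random.default_rng(seed)
    if w is None:
        w = np.resize(_DEFAULT_W, d)
    w = np.asarray(w, dtype=float)
    if w.shape != (d,):
        raise ValueError("w must have length d")

    u = rng.normal(size=d)
    u /= np.sqrt((u ** 2).sum())
    offsets = (np.arange(k_true) - (k_true - 1) / 2) * separation
    means = offsets[:, None] * u[None, :]

    z = rng.integers(0, k_true, size=n)
    X = means[z] + rng.normal(size=(n, d))
    y = (rng.random(n) < sigmoid(w0 + X @ w)).astype(int)

    n_out = int(np.floor(outlier_rate * n))
    out_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], dtype=int)
    if n_out:
        dirs = rng.normal(size=(n_out, d))
        dirs /= np.sqrt((dirs ** 2).sum(axis=1, keepdims=True))
        X[out_idx] += dirs * (10.0 + 5.0 * separation)

    miss = rng.random((n, d)) < missing_rate
    # keep every column at least partly observed
    full = miss.all(axis=0)
    miss[0, full] = False
    Xm = X.copy()
    Xm[miss] = np.nan

    ds = TabularDataset(features=Xm, labels=y)
    truth = TabularTruth(cluster_assignments=z, w0=w0, w=w,
                         missing_mask=miss, outlier_indices=np.sort(out_idx))
    return ds, truth


def _ellipse_mask(side: int, cy: float, cx: float, ry: float, rx: float):
    yy, xx = np.mgrid[0:side, 0:side]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def gen_images(n_images: int = 40, side: int = 128, n_bands: int = 5,
               lesion_rate: float = 0.5,
               lesion_size_range: tuple[int, int] = (12, 28),
               noise_sd: float = 2.0, seed: int = 0):
    """Generate banded grayscale images with optional bright lesions.

    Band levels span 20..180 (8-bit); lesions render at 245, brighter than
    every band. Returns (list of uint8 (side, side) arrays, list of
    ImageTruth).
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if side < 32:
        raise ValueError("side must be >= 32")
    lo, hi = lesion_size_range
    if not (1 <= lo <= hi < side):
        raise ValueError("invalid lesion_size_range")
    rng = np.random.default_rng(seed)
    levels = np.round(np.linspace(20, 180, n_bands)).astype(float)
    lesion_level = 245.0

    edges = np.rint(np.linspace(0, side, n_bands + 1)).astype(int)
    base = np.empty((side, side))
    for b in range(n_bands):
        base[edges[b]:edges[b + 1], :] = levels[b]

    images, truths = [], []
    for _ in range(n_images):
        img = base.copy()
        boxes: list[tuple[float, float, float, float]] = []
        if rng.random() < lesion_rate:
            for _ in range(int(rng.integers(1, 4))):
                w = float(rng.integers(lo, hi + 1))
                h = float(rng.integers(lo, hi + 1))
                rx, ry = w / 2, h / 2
                cx = float(rng.uniform(rx, side - rx))
                cy = float(rng.uniform(ry, side - ry))
                mask = _ellipse_mask(side, cy, cx, ry, rx)
                img[mask] = lesion_level
                rows, cols = np.nonzero(mask)
                boxes.append((float(cols.min()), float(rows.min()),
                              float(cols.max() + 1), float(rows.max() + 1)))
        if noise_sd > 0:
            img = img + rng.normal(0, noise_sd, size=img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        images.append(img)
        truths.append(ImageTruth(boxes=boxes, affected=bool(boxes),
                                 band_levels=levels.copy()))
    return images, truths
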