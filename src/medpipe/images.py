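"""Intensity-quantization image pipeline.

Stage 1 of the detection arm: 1-D k-means over pixel intensities (the
feature space is intensity only — grayscale radiograph structure is carried
by a handful of gray-level bands), rendering of the quantized "clustered
image", outlier-pixel suppression, resize + [0,1] normalization, per-cluster
region features, and a 2-channel stack that appends the pixel-group label as
an extra feature channel.

Cluster labels are canonicalized so cluster 0 is the darkest (ascending
cluster mean), making labels stable across runs and seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .kmeans import KMeansConfig, assign_points, fit_parallel

_DEPTH_DTYPES = {8: np.uint8, 16: np.uint16}


def _check_image(img) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    return img


def bit_depth(img: np.ndarray) -> int:
    """Infer bit depth (8 or 16) from dtype or value range."""
    if img.dtype == np.uint8:
        return 8
    if img.dtype == np.uint16:
        return 16
    return 8 if img.max() <= 255 else 16


@dataclass
class ClusterMap:
    """Per-pixel cluster labels plus ascending cluster mean intensities."""

    labels: np.ndarray        # (H, W) ints in 0..k-1
    cluster_means: np.ndarray # (k,) sorted ascending
    k: int

    def to_dict(self) -> dict:
        return {"cluster_means": self.cluster_means.tolist(), "k": int(self.k)}


@dataclass
class RegionFeatures:
    """Per-cluster region statistics: occupancy, location and texture."""

    cluster: int
    area: int
    centroid: tuple[float, float]          # (row, col)
    bbox: tuple[int, int, int, int]        # (min_row, min_col, max_row, max_col) inclusive
    mean_intensity: float
    intensity_variance: float
    aspect_ratio: float                    # bbox width / height


def cluster_pixels(img, k: int = 5, n_chunks: int = 1, seed: int = 0,
                   max_rounds: int = 100,
                   shift_threshold: float = 1e-6) -> ClusterMap:
    """Quantize an image into k intensity clusters with chunked k-means.

    Initial centroids are sampled (seeded) from the *distinct* intensity
    values, so an image of flat plateaus can never seed two centroids inside
    one plateau. If the image has fewer distinct intensities than k, k is
    reduced with a warning.
    """
    img = _check_image(img)
    values = img.reshape(-1, 1).astype(float)
    uniq = np.unique(values)
    if uniq.size < k:
        warnings.warn(
            f"image has {uniq.size} distinct intensities < k={k}; reducing k",
            stacklevel=2,
        )
        k = int(uniq.size)
    rng = np.random.default_rng(seed)
    init = np.sort(rng.choice(uniq, size=k, replace=False)).reshape(-1, 1)
    cfg = KMeansConfig(k=k, max_rounds=max_rounds,
                       shift_threshold=shift_threshold,
                       n_chunks=n_chunks, seed=seed)
    model = fit_parallel(values, cfg, init=init)
    labels = assign_points(values, model.centroids)
    # darkest-first canonical order
    order = np.argsort(model.centroids[:, 0], kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return ClusterMap(labels=remap[labels].reshape(img.shape),
                      cluster_means=model.centroids[order, 0].copy(), k=k)


def render_clustered(img, cmap: ClusterMap) -> np.ndarray:
    """Replace each pixel by its cluster's mean intensity (rounded to depth)."""
    img = _check_image(img)
    if cmap.labels.shape != img.shape:
        raise ValueError("image and cluster map shapes differ")
    depth = bit_depth(img)
    vals = np.clip(np.rint(cmap.cluster_means), 0, 2 ** depth - 1)
    return vals[cmap.labels].astype(_DEPTH_DTYPES[depth])


def remove_outlier_pixels(img, cmap: ClusterMap, t: float = 3.0) -> np.ndarray:
    """Replace pixels deviating from their cluster mean by more than
    t * (cluster std) with the cluster mean."""
    if t <= 0:
        raise ValueError("t must be positive")
    img = _check_image(img)
    if cmap.labels.shape != img.shape:
        raise ValueError("image and cluster map shapes differ")
    out = img.astype(float).copy()
    depth = bit_depth(img)
    for j in range(cmap.k):
        mask = cmap.labels == j
        if not mask.any():
            continue
        vals = out[mask]
        mu = vals.mean()
        sd = vals.std()
        dev = np.abs(vals - mu)
        vals[dev > t * sd] = mu
        out[mask] = vals
    return np.clip(np.rint(out), 0, 2 ** depth - 1).astype(img.dtype)


def resize_normalize(img, side: int = 640) -> np.ndarray:
    """Bilinear resize to side x side, then min-max scale to [0, 1]
    (constant images map to all zeros)."""
    if side < 1:
        raise ValueError("side must be >= 1")
    img = _check_image(img).astype(float)
    resized = _sk_resize(img, (side, side), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    lo, hi = resized.min(), resized.max()
    if hi == lo:
        return np.zeros_like(resized)
    return (resized - lo) / (hi - lo)


def extract_region_features(cmap: ClusterMap, img) -> list[RegionFeatures]:
    """Per-cluster area, centroid, bounding box, intensity stats and bbox
    aspect ratio; areas sum to H*W."""
    img = _check_image(img)
    if cmap.labels.shape != img.shape:
        raise ValueError("image and cluster map shapes differ")
    feats = []
    for j in range(cmap.k):
        mask = cmap.labels == j
        area = int(mask.sum())
        if area == 0:
            feats.append(RegionFeatures(j, 0, (float("nan"),) * 2,
                                        (0, 0, -1, -1), float("nan"),
                                        float("nan"), float("nan")))
            continue
        rows, cols = np.nonzero(mask)
        vals = img[mask].astype(float)
        bbox = (int(rows.min()), int(cols.min()),
                int(rows.max()), int(cols.max()))
        h = bbox[2] - bbox[0] + 1
        w = bbox[3] - bbox[1] + 1
        feats.append(RegionFeatures(
            cluster=j, area=area,
            centroid=(float(rows.mean()), float(cols.mean())),
            bbox=bbox,
            mean_intensity=float(vals.mean()),
            intensity_variance=float(vals.var()),
            aspect_ratio=w / h,
        ))
    return feats


def augment_pixel_group_channel(img, cmap: ClusterMap) -> np.ndarray:
    """Stack (H, W, 2): channel 0 = min-max normalized intensities,
    channel 1 = cluster labels scaled to [0, 1] (all zeros when k=1)."""
    img = _check_image(img).astype(float)
    if cmap.labels.shape != img.shape:
        raise ValueError("image and cluster map shapes differ")
    lo, hi = img.min(), img.max()
    ch0 = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    ch1 = (np.zeros_like(img) if cmap.k == 1
           else cmap.labels.astype(float) / (cmap.k - 1))
    return np.stack([ch0, ch1], axis=-1)
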