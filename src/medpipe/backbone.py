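"""Tiny trainable reference backbone for the detection geometry.

This is a deliberately small predictor satisfying the backbone contract
(image -> tensor of shape (S, S, A, 5 + C)), used to exercise the decoding,
NMS and flagging machinery end to end on synthetic images. It is a
hand-rolled model of cell-level intensity statistics, not a convolutional
network: per grid cell it extracts [mean, std, max, bright-fraction] from
the resized image on a fixed intensity scale, scores objectness with the
package's own gradient-ascent logistic regression (trained on a
class-balanced sample of cells), regresses the cell-relative box encoding by
least squares on the positive cells, and emits the empirical training class
distribution as the class posterior.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from ._seeds import derive_seed
from .detection import GridSpec, encode_box
from .images import bit_depth
from .logistic import fit_gd, predict_proba


def _cell_edges(side: int, S: int) -> np.ndarray:
    return np.rint(np.linspace(0, side, S + 1)).astype(int)


class TinyLesionBackbone:
    """Cell-statistics backbone for bright-lesion detection.

    Parameters
    ----------
    spec : GridSpec
        Grid geometry; ``spec.image_side`` is the working resolution.
    n_steps : int, default=200
        Gradient-ascent iterations for the objectness head.
    alpha : float, default=1.0
        Learning rate of the objectness head.
    bright_quantile : float, default=0.85
        Intensity (on the fixed [0, 1] scale) above which a pixel counts as
        "bright" for the bright-fraction feature.
    random_state : int, default=0
    """

    def __init__(self, spec: GridSpec, n_steps: int = 200, alpha: float = 1.0,
                 bright_quantile: float = 0.85, random_state: int = 0):
        self.spec = spec
        self.n_steps = n_steps
        self.alpha = alpha
        self.bright_quantile = bright_quantile
        self.random_state = random_state

    # -- featurization ----------------------------------------------------
    def _resize(self, img: np.ndarray) -> np.ndarray:
        side = int(self.spec.image_side)
        scale = 2 ** bit_depth(np.asarray(img)) - 1
        out = _sk_resize(np.asarray(img, dtype=float), (side, side), order=1,
                         mode="edge", anti_aliasing=False, preserve_range=True)
        return out / scale   # fixed scale: comparable across images

    def cell_features(self, img: np.ndarray) -> np.ndarray:
        """(S*S, 4) array of per-cell [mean, std, max, bright fraction]."""
        x = self._resize(img)
        S = self.spec.S
        edges = _cell_edges(x.shape[0], S)
        feats = np.empty((S * S, 4))
        i = 0
        for r in range(S):
            for c in range(S):
                patch = x[edges[r]:edges[r + 1], edges[c]:edges[c + 1]]
                feats[i] = (patch.mean(), patch.std(), patch.max(),
                            (patch > self.bright_quantile).mean())
                i += 1
        return feats

    # -- training ---------------------------------------------------------
    def fit(self, images, truths):
        """Train on images with ground truth [(box, class_id), ...] lists.

        Boxes are absolute pixel corners in the original image coordinates.
        """
        S = self.spec.S
        feats, labels, pos_feats, pos_targets, classes = [], [], [], [], []
        for img, truth in zip(images, truths):
            img = np.asarray(img)
            f = self.cell_features(img)
            sx = self.spec.image_side / img.shape[1]
            sy = self.spec.image_side / img.shape[0]
            cell_label = np.zeros(S * S)
            for box, cls in truth:
                b = (box[0] * sx, box[1] * sy, box[2] * sx, box[3] * sy)
                cell, enc = encode_box(b, self.spec)
                idx = cell[0] * S + cell[1]
                cell_label[idx] = 1
                pos_feats.append(f[idx])
                pos_targets.append([enc.bx, enc.by,
                                    np.log(enc.bw), np.log(enc.bh)])
                classes.append(int(cls))
            feats.append(f)
            labels.append(cell_label)
        X = np.vstack(feats)
        y = np.concatenate(labels)

        # balance classes: all positive cells + an equal seeded negative draw
        rng = np.random.default_rng(derive_seed(self.random_state, "balance"))
        pos_idx = np.where(y == 1)[0]
        neg_idx = np.where(y == 0)[0]
        n_neg = min(neg_idx.size, max(pos_idx.size, 1))
        neg_sample = rng.choice(neg_idx, size=n_neg, replace=False)
        sel = np.concatenate([pos_idx, neg_sample])
        self.obj_model_ = fit_gd(
            X[sel], y[sel], alpha=self.alpha, max_iters=self.n_steps,
            tol=0.0, seed=derive_seed(self.random_state, "objhead"))

        if pos_feats:
            A = np.column_stack([np.ones(len(pos_feats)),
                                 np.asarray(pos_feats)])
            T = np.asarray(pos_targets)
            self.box_coef_, *_ = np.linalg.lstsq(A, T, rcond=None)
            counts = np.bincount(classes, minlength=self.spec.n_classes)
            self.class_probs_ = counts / counts.sum()
        else:
            self.box_coef_ = None
            self.class_probs_ = np.full(self.spec.n_classes,
                                        1 / self.spec.n_classes)
        return self

    # -- inference --------------------------------------------------------
    def __call__(self, img) -> np.ndarray:
        if not hasattr(self, "obj_model_"):
            raise ValueError("TinyLesionBackbone is not fitted yet")
        S, A, C = self.spec.S, self.spec.n_anchors, self.spec.n_classes
        f = self.cell_features(np.asarray(img))
        pobj = predict_proba(self.obj_model_, f)
        tensor = np.zeros((S, S, A, 5 + C))
        tensor[..., 5:] = 1.0 / C      # inert anchor slots stay uniform
        if self.box_coef_ is not None:
            enc = np.column_stack([np.ones(f.shape[0]), f]) @ self.box_coef_
        else:
            enc = np.tile([0.5, 0.5, np.log(0.5), np.log(0.5)], (f.shape[0], 1))
        i = 0
        for r in range(S):
            for c in range(S):
                tensor[r, c, 0, 0] = pobj[i]
                tensor[r, c, 0, 1] = np.clip(enc[i, 0], 0, 1)
                tensor[r, c, 0, 2] = np.clip(enc[i, 1], 0, 1)
                tensor[r, c, 0, 3] = np.exp(np.clip(enc[i, 2], -5, 5))
                tensor[r, c, 0, 4] = np.exp(np.clip(enc[i, 3], -5, 5))
                tensor[r, c, 0, 5:] = self.class_probs_
                i += 1
        return tensor
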