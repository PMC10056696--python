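"""Grid-based single-shot detection geometry.

The image is divided into an S x S grid; the cell containing an object's
center is responsible for predicting it. Boxes are encoded cell-relatively:
(bx, by) are the center offsets within the owning cell in [0, 1], and
(bw, bh) are the box width/height *relative to the cell size* (note: classic
single-shot detectors scale bw/bh by the image; here the cell-size
convention is used throughout, with exact encode/decode round trips).

A detection carries an objectness probability pobj in [0, 1], class
probabilities summing to 1, and a confidence defined as the product
Pr(class | obj) * Pr(obj) * IoU. Redundant detections are removed per class
by greedy non-maximum suppression. Anchor priors are derived by clustering
ground-truth (w, h) pairs under the 1 - IoU distance of co-centered boxes.

Absolute boxes are corner tuples (x1, y1, x2, y2) in pixels, x to the right
and y downward, with exclusive continuous upper corners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kmeans import init_centroids, KMeansConfig


@dataclass
class GridSpec:
    """Detection grid: side S, image side in pixels, anchor (w, h) priors and
    class count. Cells have real-valued size image_side / S."""

    S: int = 7
    image_side: float = 640.0
    anchors: list[tuple[float, float]] = field(
        default_factory=lambda: [(32.0, 32.0), (64.0, 64.0), (128.0, 128.0)])
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not self.anchors:
            raise ValueError("anchors must be non-empty")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")

    @property
    def cell_size(self) -> float:
        return self.image_side / self.S

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class BoundingBox:
    """Cell-relative box: center offsets bx, by in [0, 1]; width/height
    bw, bh in cell-size units (positive)."""

    bx: float
    by: float
    bw: float
    bh: float

    def __post_init__(self) -> None:
        if not (0 <= self.bx <= 1 and 0 <= self.by <= 1):
            raise ValueError("bx, by must lie in [0, 1]")
        if self.bw <= 0 or self.bh <= 0:
            raise ValueError("bw, bh must be positive")


@dataclass(eq=False)
class Detection:
    """A decoded detection: absolute box, objectness, class posteriors."""

    box: tuple[float, float, float, float]   # (x1, y1, x2, y2) pixels
    pobj: float
    class_probs: np.ndarray
    conf: float = 0.0
    class_id: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pobj <= 1):
            raise ValueError("pobj must lie in [0, 1]")
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        if abs(self.class_probs.sum() - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        self.class_id = int(np.argmax(self.class_probs))

    def to_dict(self, image_id=None) -> dict:
        x1, y1, x2, y2 = self.box
        d = {"class_id": self.class_id, "x": x1, "y": y1,
             "w": x2 - x1, "h": y2 - y1,
             "pobj": float(self.pobj), "conf": float(self.conf)}
        if image_id is not None:
            d["image_id"] = image_id
        return d


def owning_cell(center, spec: GridSpec) -> tuple[int, int]:
    """Cell (row, col) whose half-open interval contains the center point;
    the far image edge belongs to the last cell."""
    x, y = float(center[0]), float(center[1])
    if not (0 <= x <= spec.image_side and 0 <= y <= spec.image_side):
        raise ValueError("point outside image bounds")
    c = spec.cell_size
    col = min(int(x // c), spec.S - 1)
    row = min(int(y // c), spec.S - 1)
    return row, col


def encode_box(abs_box, spec: GridSpec):
    """Encode an absolute (x1, y1, x2, y2) box as (cell, BoundingBox)."""
    x1, y1, x2, y2 = (float(v) for v in abs_box)
    if x2 <= x1 or y2 <= y1:
        raise ValueError("box must have positive extent")
    cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
    row, col = owning_cell((cx, cy), spec)
    c = spec.cell_size
    return (row, col), BoundingBox(
        bx=cx / c - col, by=cy / c - row,
        bw=(x2 - x1) / c, bh=(y2 - y1) / c,
    )


def decode_box(cell, b: BoundingBox, spec: GridSpec):
    """Inverse of :func:`encode_box` (exact round trip)."""
    row, col = cell
    c = spec.cell_size
    cx, cy = (col + b.bx) * c, (row + b.by) * c
    w, h = b.bw * c, b.bh * c
    return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def iou(a, b) -> float:
    """Intersection over union of two corner boxes; disjoint boxes -> 0."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = (ax2 - ax1) * (ay2 - ay1)
    area_b = (bx2 - bx1) * (by2 - by1)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("degenerate zero-area box")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def confidence(p_class_given_obj: float, p_obj: float, iou_val: float) -> float:
    """conf = Pr(class | obj) * Pr(obj) * IoU, each factor in [0, 1]."""
    for v in (p_class_given_obj, p_obj, iou_val):
        if not (0 <= v <= 1):
            raise ValueError("confidence factors must lie in [0, 1]")
    return p_class_given_obj * p_obj * iou_val


def nms(dets: list[Detection], iou_thresh: float = 0.5,
        obj_thresh: float = 0.5) -> list[Detection]:
    """Greedy per-class non-maximum suppression.

    Detections with pobj below ``obj_thresh`` are dropped; per class the
    highest-confidence survivor suppresses others overlapping it with
    IoU > ``iou_thresh``. Ties break by (conf, then input index). The result
    is sorted by confidence descending.
    """
    if not (0 <= iou_thresh <= 1 and 0 <= obj_thresh <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    kept: list[tuple[float, int, Detection]] = []
    by_class: dict[int, list[tuple[float, int, Detection]]] = {}
    for idx, d in enumerate(dets):
        if d.pobj < obj_thresh:
            continue
        by_class.setdefault(d.class_id, []).append((d.conf, idx, d))
    for cls, cands in by_class.items():
        cands.sort(key=lambda t: (-t[0], t[1]))
        survivors: list[tuple[float, int, Detection]] = []
        for conf_i, idx_i, d_i in cands:
            if all(iou(d_i.box, s[2].box) <= iou_thresh for s in survivors):
                survivors.append((conf_i, idx_i, d_i))
        kept.extend(survivors)
    kept.sort(key=lambda t: (-t[0], t[1]))
    return [d for _, _, d in kept]


def _centered(wh) -> tuple[float, float, float, float]:
    w, h = wh
    return (-w / 2, -h / 2, w / 2, h / 2)


def anchors_from_boxes(gt_boxes, m: int, seed: int = 0,
                       max_rounds: int = 100) -> np.ndarray:
    """Derive m anchor (w, h) priors by clustering ground-truth box shapes.

    Lloyd iteration with the shape distance d = 1 - IoU of co-centered boxes
    (seeded row-sampling init shared with the k-means module; mean update).
    Anchors come back sorted by area ascending.
    """
    WH = np.asarray(gt_boxes, dtype=float)
    if WH.ndim != 2 or WH.shape[1] != 2:
        raise ValueError("gt_boxes must be an (n, 2) array of (w, h)")
    if WH.shape[0] < m:
        raise ValueError(f"need at least m={m} boxes, got {WH.shape[0]}")
    anchors = init_centroids(WH, KMeansConfig(k=m, seed=seed))
    labels = None
    for _ in range(max_rounds):
        dist = np.array([[1 - iou(_centered(wh), _centered(a))
                          for a in anchors] for wh in WH])
        new_labels = np.argmin(dist, axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(m):
            mask = labels == j
            if mask.any():
                anchors[j] = WH[mask].mean(axis=0)
    order = np.argsort(anchors[:, 0] * anchors[:, 1], kind="stable")
    return anchors[order]


def _match(preds: list[Detection], truths, spec: GridSpec):
    """Match each truth box to the best-IoU prediction in its owning cell."""
    pairs = []
    pred_cells = [owning_cell((((p.box[0] + p.box[2]) / 2),
                               ((p.box[1] + p.box[3]) / 2)), spec)
                  for p in preds]
    for t_box, t_cls in truths:
        cell = owning_cell((((t_box[0] + t_box[2]) / 2),
                            ((t_box[1] + t_box[3]) / 2)), spec)
        best, best_iou = None, -1.0
        for p, p_cell in zip(preds, pred_cells):
            if p_cell != cell:
                continue
            v = iou(p.box, t_box)
            if v > best_iou:
                best, best_iou = p, v
        if best is not None:
            pairs.append((best, t_box, int(t_cls)))
    return pairs


def detection_loss(preds: list[Detection], truths, spec: GridSpec) -> dict:
    """MSE localization + cross-entropy classification loss over matched
    prediction/truth pairs.

    ``truths`` is a list of ((x1, y1, x2, y2), class_id). loc_mse is the mean
    squared error over the encoded (bx, by, bw, bh) of matched pairs;
    cls_xent is the mean -log p(true class).
    """
    if not truths:
        if preds:
            raise ValueError("empty truth with non-empty prediction set")
        return {"loc_mse": 0.0, "cls_xent": 0.0, "total": 0.0}
    pairs = _match(preds, truths, spec)
    if not pairs:
        return {"loc_mse": float("nan"), "cls_xent": float("nan"),
                "total": float("nan")}
    sq, xent = [], []
    for p, t_box, t_cls in pairs:
        _, bp = encode_box(p.box, spec)
        _, bt = encode_box(t_box, spec)
        sq.extend([(bp.bx - bt.bx) ** 2, (bp.by - bt.by) ** 2,
                   (bp.bw - bt.bw) ** 2, (bp.bh - bt.bh) ** 2])
        xent.append(-math.log(max(float(p.class_probs[t_cls]), 1e-12)))
    loc = float(np.mean(sq))
    ce = float(np.mean(xent))
    return {"loc_mse": loc, "cls_xent": ce, "total": loc + ce}


def decode_tensor(tensor: np.ndarray, spec: GridSpec,
                  clip: bool = True) -> list[Detection]:
    """Decode a backbone output tensor of shape (S, S, A, 5 + C) into
    candidate detections.

    Channel layout per anchor: [pobj, bx, by, bw, bh, class probs...].
    Confidence is pobj * max class prob (the IoU factor is unknown at
    inference and treated as 1). Anchor slots with pobj = 0 are skipped.
    """
    expected = (spec.S, spec.S, spec.n_anchors, 5 + spec.n_classes)
    if tensor.shape != expected:
        raise ValueError(
            f"backbone output shape {tensor.shape} != expected {expected}")
    dets = []
    for row in range(spec.S):
        for col in range(spec.S):
            for a in range(spec.n_anchors):
                v = tensor[row, col, a]
                pobj = float(v[0])
                if pobj <= 0:
                    continue
                bx, by, bw, bh = (float(x) for x in v[1:5])
                if clip:
                    bx = min(max(bx, 0.0), 1.0)
                    by = min(max(by, 0.0), 1.0)
                    bw = max(bw, 1e-6)
                    bh = max(bh, 1e-6)
                probs = np.clip(v[5:], 0, None)
                s = probs.sum()
                probs = (probs / s) if s > 0 else np.full(spec.n_classes,
                                                          1 / spec.n_classes)
                box = decode_box((row, col), BoundingBox(bx, by, bw, bh), spec)
                d = Detection(box=box, pobj=min(pobj, 1.0), class_probs=probs)
                d.conf = confidence(float(probs.max()), d.pobj, 1.0)
                dets.append(d)
    return dets


def detect_and_flag(img, backbone, spec: GridSpec, covid_class_id: int = 0,
                    obj_thresh: float = 0.5, iou_thresh: float = 0.5):
    """Run a backbone on an image, decode + NMS, and flag the image as
    "affected" iff at least one surviving detection carries the disease
    class.

    ``backbone`` is any callable image -> (S, S, A, 5 + C) tensor.
    Returns (detections, flag) with flag in {"affected", "non-affected"}.
    """
    tensor = np.asarray(backbone(img), dtype=float)
    dets = decode_tensor(tensor, spec)
    dets = nms(dets, iou_thresh=iou_thresh, obj_thresh=obj_thresh)
    affected = any(d.class_id == covid_class_id for d in dets)
    return dets, ("affected" if affected else "non-affected")
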