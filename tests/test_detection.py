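"""Detection geometry: cells, box codecs, IoU, NMS vs a brute-force oracle,
anchors, losses, and the affected/non-affected flagger."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medpipe.detection import (BoundingBox, Detection, GridSpec,
                               anchors_from_boxes, confidence, decode_box,
                               detect_and_flag, detection_loss, encode_box,
                               iou, nms, owning_cell)

SPEC = GridSpec(S=7, image_side=70.0, anchors=[(10.0, 10.0)], n_classes=3)


def _rand_box(g, side=70.0):
    w = g.uniform(2, side / 2)
    h = g.uniform(2, side / 2)
    cx = g.uniform(w / 2, side - w / 2)
    cy = g.uniform(h / 2, side - h / 2)
    return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


class TestOwningCell:
    def test_origin_in_first_cell(self):
        assert owning_cell((0.0, 0.0), SPEC) == (0, 0)

    def test_interior_boundary_belongs_to_higher_cell(self):
        # cell size 10: x=10 starts column 1
        assert owning_cell((10.0, 0.0), SPEC) == (0, 1)

    def test_far_edge_clamped_to_last_cell(self):
        assert owning_cell((70.0, 70.0), SPEC) == (6, 6)

    def test_matches_floor_division_oracle(self, rng):
        for _ in range(100):
            x, y = rng.uniform(0, 69.99, size=2)
            want = (int(y // 10), int(x // 10))
            assert owning_cell((x, y), SPEC) == want

    def test_outside_image_rejected(self):
        with pytest.raises(ValueError):
            owning_cell((71.0, 0.0), SPEC)


class TestBoxCodec:
    def test_cell_sized_centered_box(self):
        # box centered in cell (2, 3) with extent exactly one cell
        box = (30.0, 20.0, 40.0, 30.0)
        cell, b = encode_box(box, SPEC)
        assert cell == (2, 3)
        assert (b.bx, b.by, b.bw, b.bh) == (0.5, 0.5, 1.0, 1.0)

    def test_full_image_box_with_s1(self):
        spec1 = GridSpec(S=1, image_side=70.0, anchors=[(70.0, 70.0)])
        cell, b = encode_box((0, 0, 70, 70), spec1)
        assert cell == (0, 0)
        assert (b.bx, b.by, b.bw, b.bh) == (0.5, 0.5, 1.0, 1.0)

    def test_roundtrip_identity_on_random_boxes(self):
        g = np.random.default_rng(0)
        for _ in range(200):
            box = _rand_box(g)
            cell, b = encode_box(box, SPEC)
            back = decode_box(cell, b, SPEC)
            np.testing.assert_allclose(back, box, atol=1e-9)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            encode_box((5, 5, 5, 9), SPEC)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_offset_two_by_two(self):
        # 2x2 boxes offset by 1 in x: intersection 2, union 6
        assert iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 2), (0, 0, 1, 1))


class TestConfidence:
    def test_all_ones(self):
        assert confidence(1.0, 1.0, 1.0) == 1.0

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, 0, 1), (1, 1, 0)])
    def test_any_zero_factor_zeroes_confidence(self, args):
        assert confidence(*args) == 0.0

    def test_product_example(self):
        assert confidence(0.8, 0.9, 0.5) == pytest.approx(0.36)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_each_factor(self, a, b, c, bump):
        base = confidence(a, b, c)
        assert confidence(min(a + bump, 1.0), b, c) >= base

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confidence(1.2, 0.5, 0.5)


def _rand_detections(seed, n=200, n_classes=3, side=70.0):
    g = np.random.default_rng(seed)
    dets = []
    for _ in range(n):
        probs = g.dirichlet(np.ones(n_classes))
        d = Detection(box=_rand_box(g, side), pobj=float(g.random()),
                      class_probs=probs)
        d.conf = d.pobj * float(probs.max())
        dets.append(d)
    return dets


def _nms_oracle(dets, iou_thresh, obj_thresh):
    """Exhaustive per-class reference: repeatedly scan for the best-remaining
    detection and delete everything it suppresses."""
    out = []
    for cls in {d.class_id for d in dets}:
        remaining = [(i, d) for i, d in enumerate(dets)
                     if d.class_id == cls and d.pobj >= obj_thresh]
        while remaining:
            best = min(remaining, key=lambda t: (-t[1].conf, t[0]))
            out.append(best)
            remaining = [(i, d) for i, d in remaining
                         if i != best[0] and iou(d.box, best[1].box) <= iou_thresh]
    out.sort(key=lambda t: (-t[1].conf, t[0]))
    return [d for _, d in out]


class TestNMS:
    def test_single_detection_kept(self):
        (d,) = _rand_detections(0, n=1)
        d.pobj = 0.9
        assert nms([d], 0.5, 0.5) == [d]

    def test_duplicate_boxes_keep_higher_confidence(self):
        g = np.random.default_rng(1)
        box = _rand_box(g)
        lo = Detection(box=box, pobj=0.8, class_probs=[1.0, 0.0])
        hi = Detection(box=box, pobj=0.9, class_probs=[1.0, 0.0])
        lo.conf, hi.conf = 0.4, 0.9
        assert nms([lo, hi], 0.5, 0.5) == [hi]

    def test_below_objectness_threshold_dropped(self):
        dets = _rand_detections(2, n=20)
        out = nms(dets, 0.5, obj_thresh=1.0)
        assert out == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        dets = _rand_detections(seed)
        got = nms(dets, iou_thresh=0.5, obj_thresh=0.5)
        want = _nms_oracle(dets, 0.5, 0.5)
        assert got == want

    def test_output_subset_with_no_overlapping_survivors(self):
        dets = _rand_detections(99)
        out = nms(dets, 0.45, 0.3)
        assert all(d in dets for d in out)
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                if a.class_id == b.class_id:
                    assert iou(a.box, b.box) <= 0.45


class TestAnchors:
    def test_identical_boxes_collapse(self):
        wh = np.tile([8.0, 12.0], (10, 1))
        anchors = anchors_from_boxes(wh, m=2, seed=0)
        np.testing.assert_allclose(anchors, [[8, 12], [8, 12]])

    def test_two_size_groups_recovered(self):
        g = np.random.default_rng(0)
        small = g.uniform(4, 6, size=(30, 2))
        large = g.uniform(30, 34, size=(30, 2))
        anchors = anchors_from_boxes(np.vstack([small, large]), m=2, seed=0)
        np.testing.assert_allclose(anchors[0], small.mean(axis=0), rtol=0.1)
        np.testing.assert_allclose(anchors[1], large.mean(axis=0), rtol=0.1)

    def test_sorted_by_area(self, rng):
        wh = rng.uniform(2, 40, size=(25, 2))
        anchors = anchors_from_boxes(wh, m=3, seed=1)
        areas = anchors[:, 0] * anchors[:, 1]
        assert (np.diff(areas) >= 0).all()

    def test_too_few_boxes_rejected(self):
        with pytest.raises(ValueError):
            anchors_from_boxes([[3.0, 3.0]], m=2)


class TestDetectionLoss:
    def _truth_and_perfect_pred(self):
        box = (22.0, 12.0, 38.0, 26.0)
        d = Detection(box=box, pobj=1.0,
                      class_probs=[1.0 - 2e-12, 1e-12, 1e-12])
        return [d], [(box, 0)]

    def test_perfect_prediction_zero_loss(self):
        preds, truths = self._truth_and_perfect_pred()
        loss = detection_loss(preds, truths, SPEC)
        assert loss["loc_mse"] == 0.0
        assert loss["cls_xent"] == pytest.approx(0.0, abs=1e-9)

    def test_uniform_class_probs_give_log_c(self):
        box = (22.0, 12.0, 38.0, 26.0)
        d = Detection(box=box, pobj=1.0, class_probs=np.full(3, 1 / 3))
        loss = detection_loss([d], [(box, 1)], SPEC)
        assert loss["cls_xent"] == pytest.approx(np.log(3))

    def test_matches_summation_oracle(self):
        g = np.random.default_rng(3)
        truths, preds = [], []
        for _ in range(5):
            t = _rand_box(g)
            cx = (t[0] + t[2]) / 2
            cy = (t[1] + t[3]) / 2
            # prediction jittered but kept in the same owning cell
            p_box = (t[0] + 0.5, t[1] + 0.5, t[2] + 0.5, t[3] + 0.5)
            if owning_cell(((p_box[0] + p_box[2]) / 2,
                            (p_box[1] + p_box[3]) / 2), SPEC) != \
                    owning_cell((cx, cy), SPEC):
                p_box = t
            probs = g.dirichlet(np.ones(3))
            preds.append(Detection(box=p_box, pobj=0.9, class_probs=probs))
            truths.append((t, int(g.integers(0, 3))))
        loss = detection_loss(preds, truths, SPEC)
        # oracle: explicit per-pair summation
        sq, ce = [], []
        for p, (t, cls) in zip(preds, truths):
            _, bp = encode_box(p.box, SPEC)
            _, bt = encode_box(t, SPEC)
            sq += [(bp.bx - bt.bx) ** 2, (bp.by - bt.by) ** 2,
                   (bp.bw - bt.bw) ** 2, (bp.bh - bt.bh) ** 2]
            ce.append(-np.log(p.class_probs[cls]))
        assert loss["loc_mse"] == pytest.approx(np.mean(sq))
        assert loss["cls_xent"] == pytest.approx(np.mean(ce))
        assert loss["total"] == pytest.approx(loss["loc_mse"] +
                                              loss["cls_xent"])

    def test_empty_truth_with_predictions_rejected(self):
        preds, _ = self._truth_and_perfect_pred()
        with pytest.raises(ValueError):
            detection_loss(preds, [], SPEC)


class TestDetectAndFlag:
    def test_silent_backbone_yields_non_affected(self):
        spec = GridSpec(S=4, image_side=64.0, anchors=[(8.0, 8.0)],
                        n_classes=2)
        backbone = lambda img: np.zeros((4, 4, 1, 7))
        dets, flag = detect_and_flag(np.zeros((64, 64)), backbone, spec)
        assert dets == [] and flag == "non-affected"

    def test_oracle_backbone_recovers_encoded_lesion(self):
        spec = GridSpec(S=4, image_side=64.0, anchors=[(8.0, 8.0)],
                        n_classes=2)
        gt = (20.0, 24.0, 34.0, 40.0)
        cell, b = encode_box(gt, spec)

        def backbone(img):
            t = np.zeros((4, 4, 1, 7))
            t[..., 5:] = 0.5
            t[cell[0], cell[1], 0] = [0.95, b.bx, b.by, b.bw, b.bh, 0.9, 0.1]
            return t

        dets, flag = detect_and_flag(np.zeros((64, 64)), backbone, spec,
                                     covid_class_id=0)
        assert flag == "affected" and len(dets) == 1
        np.testing.assert_allclose(dets[0].box, gt, atol=1e-9)

    def test_wrong_tensor_shape_rejected(self):
        spec = GridSpec(S=4, image_side=64.0, anchors=[(8.0, 8.0)],
                        n_classes=2)
        with pytest.raises(ValueError):
            detect_and_flag(np.zeros((64, 64)),
                            lambda img: np.zeros((4, 4, 2, 7)), spec)


def test_bounding_box_and_detection_invariants():
    with pytest.raises(ValueError):
        BoundingBox(bx=1.2, by=0.5, bw=1.0, bh=1.0)
    with pytest.raises(ValueError):
        Detection(box=(0, 0, 1, 1), pobj=1.5, class_probs=[1.0])
    with pytest.raises(ValueError):
        Detection(box=(0, 0, 1, 1), pobj=0.5, class_probs=[0.6, 0.6])
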