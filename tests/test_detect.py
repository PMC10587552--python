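"""Detection matching and AP/AR metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acnegrade.annotations import LesionAnnotation
from acnegrade.categories import ACNE_RELATED
from acnegrade.detect import (
    DetectionResult,
    DetectorConfig,
    count_by_category,
    detect_lesions,
    evaluate_detection,
    iou,
    match_detections,
)
from acnegrade.errors import ConfigError, InvalidBoxError

# ---------------------------------------------------------------------------
# independent oracles


def oracle_match(dets, truths, thr):
    """Greedy score-ordered matching by explicit loops."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    used = set()
    flags = []
    for i in order:
        best, best_iou = None, 0.0
        for j, t in enumerate(truths):
            if j in used or t.category != dets[i].category:
                continue
            v = iou(dets[i].bbox, t.bbox)
            if v > best_iou:
                best, best_iou = j, v
        if best is not None and best_iou >= thr:
            used.add(best)
            flags.append(True)
        else:
            flags.append(False)
    return order, flags


def oracle_ap(flag_score_pairs, n_truth):
    """All-point interpolated AP by explicit PR-point enumeration."""
    if n_truth == 0 or not flag_score_pairs:
        return 0.0
    ranked = sorted(flag_score_pairs, key=lambda r: -r[0])
    points = []
    tp = fp = 0
    for _, is_tp in ranked:
        tp += is_tp
        fp += not is_tp
        points.append((tp / n_truth, tp / (tp + fp)))
    ap, prev_r = 0.0, 0.0
    for k, (r, _) in enumerate(points):
        p_env = max(p for (r2, p) in points[k:])  # envelope: best precision at >= r
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


def oracle_evaluate(all_dets, all_truths, thr):
    cats = {t.category for ts in all_truths.values() for t in ts}
    ap, rec = {}, {}
    for cat in cats:
        pairs = []
        n_truth = sum(t.category == cat for ts in all_truths.values() for t in ts)
        n_tp = 0
        for dr in all_dets:
            truths = all_truths.get(dr.image_id, [])
            order, flags = oracle_match(dr.detections, truths, thr)
            for rank, i in enumerate(order):
                d = dr.detections[i]
                if d.category == cat:
                    pairs.append((d.score, flags[rank]))
                    n_tp += flags[rank]
        ap[cat] = oracle_ap(pairs, n_truth)
        rec[cat] = n_tp / n_truth
    return ap, rec


# ---------------------------------------------------------------------------
# iou


def _box(x, y, w, h):
    return (float(x), float(y), float(w), float(h))


class TestIoU:
    def test_identity(self):
        assert iou(_box(1, 2, 10, 5), _box(1, 2, 10, 5)) == 1.0

    def test_disjoint(self):
        assert iou(_box(0, 0, 10, 10), _box(20, 20, 5, 5)) == 0.0

    def test_half_overlap_arithmetic(self):
        # inter = 50, union = 150
        assert iou(_box(0, 0, 10, 10), _box(5, 0, 10, 10)) == pytest.approx(1 / 3, abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(InvalidBoxError):
            iou(_box(0, 0, 0, 10), _box(0, 0, 5, 5))

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 50), min_size=4, max_size=4).map(tuple),
           st.lists(st.floats(0, 50), min_size=4, max_size=4).map(tuple))
    def test_symmetry_and_bounds(self, a, b):
        a = (a[0], a[1], a[2] + 1.0, a[3] + 1.0)
        b = (b[0], b[1], b[2] + 1.0, b[3] + 1.0)
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0
        # self-IoU is 1 up to float cancellation in the edge arithmetic
        assert iou(a, a) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# matching


def _ann(cat, box, score=1.0):
    return LesionAnnotation(category=cat, bbox=box, score=score)


class TestMatching:
    def test_echoed_truths_all_tp(self):
        truths = [_ann("papule", _box(10, 10, 5, 5)), _ann("pustule", _box(30, 30, 6, 6))]
        mr = match_detections(truths, truths, 0.5)
        assert all(mr.is_tp) and mr.n_fn == 0

    def test_no_detections_all_fn(self):
        truths = [_ann("papule", _box(10 * i, 10, 5, 5)) for i in range(3)]
        mr = match_detections([], truths, 0.5)
        assert mr.is_tp == [] and mr.n_fn == 3

    def test_one_to_one_higher_score_claims_truth(self):
        truth = [_ann("papule", _box(10, 10, 10, 10))]
        dets = [
            _ann("papule", _box(11, 10, 10, 10), score=0.8),
            _ann("papule", _box(10, 11, 10, 10), score=0.9),
        ]
        mr = match_detections(dets, truth, 0.5)
        assert mr.order[0] == 1 and mr.is_tp == [True, False]

    def test_category_mismatch_is_fp(self):
        truth = [_ann("papule", _box(10, 10, 10, 10))]
        dets = [_ann("pustule", _box(10, 10, 10, 10), score=0.9)]
        mr = match_detections(dets, truth, 0.5)
        assert mr.is_tp == [False] and mr.n_fn == 1

    def test_score_monotone(self, rng):
        """Raising a TP detection's score never turns it FP."""
        truths = [_ann("papule", _box(10 * j, 10, 8, 8)) for j in range(4)]
        dets = [
            _ann("papule", _box(10 * j + rng.uniform(-2, 2), 10, 8, 8), score=float(s))
            for j, s in enumerate(rng.uniform(0.2, 0.8, size=4))
        ]
        mr = match_detections(dets, truths, 0.3)
        for rank, i in enumerate(mr.order):
            if not mr.is_tp[rank]:
                continue
            boosted = [d.with_score(0.99) if k == i else d for k, d in enumerate(dets)]
            mr2 = match_detections(boosted, truths, 0.3)
            assert mr2.is_tp[mr2.order.index(i)]


# ---------------------------------------------------------------------------
# evaluation


class TestEvaluateDetection:
    def test_perfect_detections(self, cohort256):
        dets = [
            DetectionResult(s.subject_id, [a.with_score(1.0) for a in s.annotations])
            for s in cohort256[:4]
        ]
        truths = {s.subject_id: s.annotations for s in cohort256[:4]}
        m = evaluate_detection(dets, truths, 0.5)
        assert all(v == 1.0 for v in m.per_class_ap.values())
        assert all(v == 1.0 for v in m.per_class_recall.values())
        assert m.mean_ap == 1.0 and m.mean_recall == 1.0

    def test_no_detections(self, cohort256):
        truths = {s.subject_id: s.annotations for s in cohort256[:2]}
        m = evaluate_detection(
            [DetectionResult(s.subject_id, []) for s in cohort256[:2]], truths, 0.5
        )
        assert m.mean_ap == 0.0 and m.mean_recall == 0.0

    def test_hand_enumerated_ranked_tp_fp_tp(self):
        """3 ranked detections (TP, FP, TP) over 2 truths: AP by hand.

        PR points: (0.5, 1), (0.5, 0.5), (1.0, 2/3); envelope makes
        AP = 0.5 * 1 + 0.5 * 2/3 = 5/6.
        """
        truths = [_ann("papule", _box(0, 0, 10, 10)), _ann("papule", _box(40, 40, 10, 10))]
        dets = [
            _ann("papule", _box(0, 0, 10, 10), score=0.9),
            _ann("papule", _box(100, 100, 10, 10), score=0.8),
            _ann("papule", _box(40, 40, 10, 10), score=0.7),
        ]
        m = evaluate_detection([DetectionResult(0, dets)], {0: truths}, 0.5)
        assert m.per_class_ap["papule"] == pytest.approx(5 / 6, abs=1e-12)
        assert m.per_class_recall["papule"] == 1.0

    def test_oracle_equivalence_random_instances(self, rng):
        """Pooled PR evaluation matches the brute-force enumeration exactly."""
        cats = ["papule", "pustule", "atrophic_scar"]
        for _ in range(200):
            truths, dets = {}, []
            for image_id in range(int(rng.integers(1, 3))):
                n_t = int(rng.integers(1, 8))
                ts = [
                    _ann(cats[rng.integers(3)],
                         _box(rng.uniform(0, 80), rng.uniform(0, 80), rng.uniform(4, 15), rng.uniform(4, 15)))
                    for _ in range(n_t)
                ]
                n_d = int(rng.integers(0, 12))
                ds = [
                    _ann(cats[rng.integers(3)],
                         _box(rng.uniform(0, 80), rng.uniform(0, 80), rng.uniform(4, 15), rng.uniform(4, 15)),
                         score=float(rng.uniform(0.05, 1.0)))
                    for _ in range(n_d)
                ]
                truths[image_id] = ts
                dets.append(DetectionResult(image_id, ds))
            m = evaluate_detection(dets, truths, 0.5)
            o_ap, o_rec = oracle_evaluate(dets, truths, 0.5)
            for cat in o_ap:
                assert m.per_class_ap[cat] == pytest.approx(o_ap[cat], abs=1e-12)
                assert m.per_class_recall[cat] == pytest.approx(o_rec[cat], abs=1e-12)

    def test_ap_one_iff_all_truths_above_fps(self):
        truths = [_ann("papule", _box(0, 0, 10, 10)), _ann("papule", _box(40, 40, 10, 10))]
        dets = [
            _ann("papule", _box(0, 0, 10, 10), score=0.9),
            _ann("papule", _box(40, 40, 10, 10), score=0.8),
            _ann("papule", _box(100, 100, 10, 10), score=0.2),  # FP ranked below all TPs
        ]
        m = evaluate_detection([DetectionResult(0, dets)], {0: truths}, 0.5)
        assert m.per_class_ap["papule"] == 1.0


# ---------------------------------------------------------------------------
# reference detector


class TestReferenceDetector:
    def test_blank_canvas_no_detections(self):
        from acnegrade.synth import generate_face_canvas

        canvas = generate_face_canvas(128, seed=0)
        assert detect_lesions(canvas.image).detections == []

    def test_well_separated_papules_found(self):
        from acnegrade.synth import LayoutConfig, generate_face_canvas, render_lesions, sample_lesions

        canvas = generate_face_canvas(256, seed=2)
        anns = sample_lesions({"papule": 5}, canvas, LayoutConfig(max_iou_same=0.0), seed=2)
        img = render_lesions(canvas, anns, seed=2)
        mr = match_detections(detect_lesions(img), anns, 0.5)
        assert sum(mr.is_tp) == 5 and mr.n_fn == 0

    def test_end_to_end_recall_on_default_benchmark(self, cohort256):
        """Reference detector recall >= 0.9 at IoU 0.5 for all acne categories."""
        dets = [detect_lesions(s.image, image_id=s.subject_id) for s in cohort256]
        truths = {s.subject_id: s.annotations for s in cohort256}
        m = evaluate_detection(dets, truths, 0.5)
        for cat in ACNE_RELATED:
            if cat in m.per_class_recall:
                assert m.per_class_recall[cat] >= 0.9, (cat, m.per_class_recall)

    def test_unknown_detector_name(self):
        with pytest.raises(ConfigError):
            detect_lesions(np.zeros((64, 64, 3), dtype=np.uint8), DetectorConfig(name="yolo"))

    def test_non_image_input(self):
        with pytest.raises(InvalidBoxError):
            detect_lesions(np.zeros((64, 64)), DetectorConfig())


class TestCountByCategory:
    def test_empty_all_zeros(self):
        counts = count_by_category(DetectionResult(0, []))
        assert set(counts) == set(__import__("acnegrade").CATEGORIES)
        assert all(v == 0 for v in counts.values())

    def test_threshold_zero_identity_and_one_boundary(self):
        dets = DetectionResult(0, [
            _ann("papule", _box(0, 0, 5, 5), score=0.4),
            _ann("papule", _box(10, 0, 5, 5), score=0.8),
            _ann("nevus", _box(20, 0, 5, 5), score=0.6),
        ])
        assert count_by_category(dets, 0.0)["papule"] == 2
        assert count_by_category(dets, 0.5) == {**count_by_category(dets, 0.5), "papule": 1, "nevus": 1}
        assert all(v == 0 for v in count_by_category(dets, 1.0).values())
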