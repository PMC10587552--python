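"""Lesion detection and AP/AR scoring.

The reference detector is a classical color-blob segmenter calibrated to
the synthetic generator's rendering palette: each pixel is assigned to the
nearest palette entry (skin or one of the nine lesion colors), per-category
masks are split into connected components, size-gated, and converted to
scored boxes. Red components are disambiguated into papule vs pustule by
the presence of the pustule's light center dot. Learned detectors can plug
in behind the same ``detect_lesions`` contract.

Evaluation follows standard detection-benchmark practice: detections are
score-ranked and greedily matched one-to-one to same-category ground truth
at an IoU threshold (default 0.5); AP is the area under the all-point
interpolated precision-recall curve; recall is TP/(TP+FN) at the end of
the ranking; the mean AP/recall average over categories present in the
ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .annotations import LesionAnnotation
from .categories import CATEGORIES
from .errors import ConfigError, InvalidBoxError
from .synth import BACKGROUND, DEFAULT_SKIN_TONE, RENDER_SPEC

logger = logging.getLogger(__name__)

Box = tuple[float, float, float, float]


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two [x, y, w, h] boxes."""
    for b in (box_a, box_b):
        if b[2] <= 0 or b[3] <= 0:
            raise InvalidBoxError(f"degenerate box {b}")
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    # clamp: float arithmetic can land a hair above 1 for identical boxes
    return min(1.0, inter / (aw * ah + bw * bh - inter)) if inter > 0 else 0.0


@dataclass
class DetectionResult:
    """Scored detections on one image."""

    image_id: int
    detections: list[LesionAnnotation] = field(default_factory=list)


@dataclass
class DetectionMetrics:
    """Per-class and mean AP/recall at a fixed IoU threshold."""

    per_class_ap: dict[str, float]
    per_class_recall: dict[str, float]
    mean_ap: float
    mean_recall: float
    iou_threshold: float

    def to_dict(self) -> dict:
        return {
            "per_class_ap": self.per_class_ap,
            "per_class_recall": self.per_class_recall,
            "mean_ap": self.mean_ap,
            "mean_recall": self.mean_recall,
            "iou_threshold": self.iou_threshold,
        }


# ---------------------------------------------------------------------------
# reference detector


@dataclass
class DetectorConfig:
    name: str = "palette_blob"
    skin_tone: tuple[int, int, int] = DEFAULT_SKIN_TONE
    min_area_frac: float = 0.25  # min component area relative to category disc area
    score_scale: float = 60.0  # color-distance scale for confidence scores
    split_area_frac: float = 1.8  # watershed-split components above this x disc area


def _palette(config: DetectorConfig) -> tuple[np.ndarray, list[str]]:
    """(colors, labels): skin/background plus every category's render color."""
    colors = [np.array(config.skin_tone, float), np.array(BACKGROUND, float)]
    labels = ["_skin", "_background"]
    for cat in CATEGORIES:
        spec = RENDER_SPEC[cat]
        color = np.array(spec["color"], float)
        if spec["style"] == "blend":  # on-canvas color is alpha-blended into skin
            a = spec["alpha"]
            color = a * color + (1 - a) * np.array(config.skin_tone, float)
        colors.append(color)
        labels.append(cat)
    spec = RENDER_SPEC["pustule"]
    colors.append(np.array(spec["core_color"], float))
    labels.append("_pustule_core")
    return np.stack(colors), labels


def detect_lesions(
    image: np.ndarray, config: DetectorConfig | None = None, image_id: int = 0
) -> DetectionResult:
    """Run the reference palette-blob detector on one RGB image."""
    config = config or DetectorConfig()
    if config.name != "palette_blob":
        raise ConfigError(f"unknown detector {config.name!r}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidBoxError(f"expected (H, W, 3) image, got shape {img.shape}")
    colors, labels = _palette(config)
    # nearest palette entry per pixel
    d2 = ((img[:, :, None, :] - colors[None, None, :, :]) ** 2).sum(axis=-1)
    assign = np.argmin(d2, axis=-1)
    side = img.shape[0]
    scale = max(side / 256.0, 1.0 / 4.0)

    core_mask = assign == labels.index("_pustule_core")
    dets: list[LesionAnnotation] = []
    for cat in CATEGORIES:
        cat_idx = labels.index(cat)
        mask = assign == cat_idx
        if cat == "papule":  # pustule core sits inside a red disc; merge for bbox
            mask = mask | core_mask
        if not mask.any():
            continue
        r_px = max(1.0, RENDER_SPEC[cat]["r"] * scale)
        disc_area = np.pi * r_px**2
        min_area = max(1.0, config.min_area_frac * disc_area)
        lab = measure.label(mask, connectivity=2)
        for region in measure.regionprops(lab):
            if region.area < min_area:
                continue
            for sub_mask, (y0, x0, y1, x1) in _split_component(
                lab == region.label, region, r_px, disc_area * config.split_area_frac
            ):
                if sub_mask.sum() < min_area:
                    continue
                name = cat
                if cat == "papule" and (core_mask & sub_mask)[y0:y1, x0:x1].any():
                    name = "pustule"
                mean_dist = float(np.sqrt(d2[sub_mask, cat_idx]).mean())
                score = float(np.clip(1.0 - mean_dist / config.score_scale, 0.05, 0.99))
                dets.append(
                    LesionAnnotation(
                        category=name,
                        bbox=(float(x0), float(y0), float(x1 - x0), float(y1 - y0)),
                        score=score,
                    )
                )
    return DetectionResult(image_id=image_id, detections=dets)


def _split_component(comp_mask: np.ndarray, region, r_px: float, split_area: float):
    """Split an oversized blob into sub-lesions by distance-transform watershed.

    Adjacent same-color lesions fuse into one connected component; a
    component much larger than one expected disc is re-segmented from the
    local maxima of its distance transform. Yields (mask, bbox) pairs.
    """
    y0, x0, y1, x1 = region.bbox
    if region.area <= split_area:
        yield comp_mask, (y0, x0, y1, x1)
        return
    local = comp_mask[y0:y1, x0:x1]
    dist = ndimage.distance_transform_edt(local)
    coords = peak_local_max(
        dist, min_distance=max(1, int(round(0.8 * r_px))), labels=local
    )
    if len(coords) <= 1:
        yield comp_mask, (y0, x0, y1, x1)
        return
    markers = np.zeros(local.shape, dtype=int)
    for i, (py, px) in enumerate(coords, start=1):
        markers[py, px] = i
    seg = watershed(-dist, markers, mask=local)
    for lbl in range(1, len(coords) + 1):
        part = seg == lbl
        if not part.any():
            continue
        ys, xs = np.nonzero(part)
        full = np.zeros_like(comp_mask)
        full[y0:y1, x0:x1] = part
        yield full, (y0 + ys.min(), x0 + xs.min(), y0 + ys.max() + 1, x0 + xs.max() + 1)


# ---------------------------------------------------------------------------
# matching and metrics


@dataclass
class MatchResult:
    """TP/FP flags aligned with score-sorted detections, plus the FN count."""

    order: list[int]  # indices into the input detections, by descending score
    is_tp: list[bool]
    n_fn: int


def match_detections(
    dets: DetectionResult | list[LesionAnnotation],
    truths: list[LesionAnnotation],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching per category, by descending score.

    Each detection claims the unmatched same-category truth with the
    highest IoU, provided it reaches the threshold; remaining detections
    are FP and unmatched truths FN.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ConfigError("iou_threshold must be in (0, 1)")
    det_list = dets.detections if isinstance(dets, DetectionResult) else dets
    order = sorted(range(len(det_list)), key=lambda i: (-det_list[i].score, i))
    matched = [False] * len(truths)
    is_tp = []
    for i in order:
        d = det_list[i]
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truths):
            if matched[j] or t.category != d.category:
                continue
            v = iou(d.bbox, t.bbox)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            is_tp.append(True)
        else:
            is_tp.append(False)
    return MatchResult(order=order, is_tp=is_tp, n_fn=matched.count(False))


def _average_precision(tp_flags: np.ndarray, n_truth: int) -> float:
    """AP from ranked TP/FP flags via the all-point interpolated PR curve."""
    if n_truth == 0:
        return 0.0
    if tp_flags.size == 0:
        return 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(~tp_flags)
    recall = tp / n_truth
    precision = tp / (tp + fp)
    # monotone non-increasing precision envelope
    precision = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, precision):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def evaluate_detection(
    all_dets: list[DetectionResult],
    all_truths: dict[int, list[LesionAnnotation]],
    iou_threshold: float = 0.5,
) -> DetectionMetrics:
    """Pooled per-class PR evaluation across images.

    Classes absent from the ground truth are excluded from the means (and
    logged) so dataset composition does not distort the averages.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ConfigError("iou_threshold must be in (0, 1)")
    # per image, per class greedy matching; then pool ranked flags per class
    per_class_records: dict[str, list[tuple[float, bool]]] = {c: [] for c in CATEGORIES}
    per_class_truth: dict[str, int] = {c: 0 for c in CATEGORIES}
    for image_id, truths in all_truths.items():
        for t in truths:
            per_class_truth[t.category] += 1
    for dr in all_dets:
        truths = all_truths.get(dr.image_id, [])
        mr = match_detections(dr, truths, iou_threshold)
        for rank, i in enumerate(mr.order):
            d = dr.detections[i]
            per_class_records[d.category].append((d.score, mr.is_tp[rank]))

    per_class_ap: dict[str, float] = {}
    per_class_recall: dict[str, float] = {}
    for cat in CATEGORIES:
        n_truth = per_class_truth[cat]
        if n_truth == 0:
            if per_class_records[cat]:
                logger.info("class %s has detections but no ground truth; excluded", cat)
            continue
        recs = sorted(per_class_records[cat], key=lambda r: -r[0])
        flags = np.array([tp for _, tp in recs], dtype=bool)
        per_class_ap[cat] = _average_precision(flags, n_truth)
        per_class_recall[cat] = float(flags.sum() / n_truth)
    if not per_class_ap:
        raise ConfigError("no ground-truth boxes in any class")
    return DetectionMetrics(
        per_class_ap=per_class_ap,
        per_class_recall=per_class_recall,
        mean_ap=float(np.mean(list(per_class_ap.values()))),
        mean_recall=float(np.mean(list(per_class_recall.values()))),
        iou_threshold=iou_threshold,
    )


def count_by_category(
    dets: DetectionResult, score_threshold: float = 0.0
) -> dict[str, int]:
    """Per-category counts of detections at or above a score threshold."""
    if not 0.0 <= score_threshold <= 1.0:
        raise ConfigError("score_threshold must be in [0, 1]")
    counts = {c: 0 for c in CATEGORIES}
    for d in dets.detections:
        if d.score >= score_threshold:
            counts[d.category] += 1
    return counts
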