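"""Synthetic frontal-face images with ground-truth lesion annotations.

The generator emulates standardized frontal facial photography at desk
scale: an elliptical face region on a neutral background, with lesions
drawn as parameterized ellipses whose color/size/texture are
category-specific so that a classical color-blob detector can separate
them. Spatial placement follows the facial-zone priors seen clinically:
closed comedones on forehead and midface, open comedones on the forehead,
atrophic scars on the cheeks, hypertrophic scars on the jaw, and
inflammatory lesions spread over the whole face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import LesionAnnotation
from .categories import CATEGORIES, normalize_counts
from .errors import InvalidSizeError, PlacementError
from .rule import DEFAULT_RULE, GradingRuleConfig, counts_to_interval

MIN_SIDE = 64
DEFAULT_SKIN_TONE = (224, 172, 150)
BACKGROUND = (200, 200, 200)
_BASE_SIDE = 256  # reference side for the lesion size table

#: rendering parameters per category, radii in pixels at the 256 px reference
RENDER_SPEC: dict[str, dict] = {
    "open_comedone": {"r": 2.0, "color": (45, 32, 26), "style": "disc"},
    "closed_comedone": {"r": 3.0, "color": (250, 232, 208), "style": "disc"},
    "papule": {"r": 4.0, "color": (208, 62, 62), "style": "disc"},
    "pustule": {
        "r": 4.0,
        "color": (208, 62, 62),
        "style": "pustule",
        "core_color": (250, 244, 168),
        "core_frac": 0.45,
    },
    "nodule_cyst": {"r": 7.0, "color": (122, 14, 44), "style": "disc"},
    "atrophic_scar": {
        "r": 5.0,
        "color": (152, 108, 92),
        "style": "ring",
        "ring_frac": 0.55,
    },
    "hypertrophic_scar": {
        "r": 6.0,
        "color": (228, 204, 198),
        "style": "disc",
        "aspect": 1.6,
    },
    "melasma": {"r": 8.0, "color": (152, 120, 72), "style": "blend", "alpha": 0.6},
    "nevus": {"r": 2.5, "color": (84, 56, 34), "style": "disc"},
}

#: facial-zone prior per category; None means uniform over the face
ZONE_PRIOR: dict[str, tuple[str, ...] | None] = {
    "open_comedone": ("forehead",),
    "closed_comedone": ("forehead", "midface"),
    "atrophic_scar": ("cheeks",),
    "hypertrophic_scar": ("jaw",),
    "papule": None,
    "pustule": None,
    "nodule_cyst": None,
    "melasma": None,
    "nevus": None,
}


@dataclass
class LayoutConfig:
    """Spatial prior and overlap-rejection settings for lesion placement."""

    zone_weight: float = 0.8  # probability of drawing from the category zone
    max_iou_same: float = 0.3  # same-category IoU rejection cap
    max_coverage: float = 0.6  # cap on mutual box-coverage across any pair
    max_attempts: int = 300


@dataclass
class FaceCanvas:
    """A rendered face region plus its geometry, used for lesion placement."""

    image: np.ndarray  # (side, side, 3) uint8
    mask: np.ndarray  # (side, side) bool face region
    skin_tone: tuple[int, int, int]
    center: tuple[float, float]  # (cx, cy)
    axes: tuple[float, float]  # (a, b) semi-axes, x then y

    @property
    def side(self) -> int:
        return self.image.shape[0]

    def zone_mask(self, zone: str) -> np.ndarray:
        """Boolean mask of a named facial zone (subset of the face mask).

        The face ellipse is split vertically into forehead (top 30%), a
        middle band (30-70%) whose central third is the midface and lateral
        thirds the cheeks, and the jaw (bottom 20%).
        """
        side = self.side
        cx, cy = self.center
        a, b = self.axes
        yy, xx = np.mgrid[0:side, 0:side]
        t = (yy - (cy - b)) / (2.0 * b)  # 0 at face top, 1 at chin
        central = np.abs(xx - cx) <= a / 3.0
        if zone == "forehead":
            cond = t < 0.30
        elif zone == "midface":
            cond = (t >= 0.30) & (t < 0.70) & central
        elif zone == "cheeks":
            cond = (t >= 0.30) & (t < 0.70) & ~central
        elif zone == "jaw":
            cond = t >= 0.80
        else:
            raise ValueError(f"unknown facial zone {zone!r}")
        return self.mask & cond

    def zone_fraction(self, zones: tuple[str, ...]) -> float:
        """Area fraction of the union of zones within the face."""
        m = np.zeros_like(self.mask)
        for z in zones:
            m |= self.zone_mask(z)
        return float(m.sum()) / float(self.mask.sum())


def generate_face_canvas(
    side_px: int,
    skin_tone: tuple[int, int, int] = DEFAULT_SKIN_TONE,
    seed: int | np.random.Generator = 0,
) -> FaceCanvas:
    """Render an elliptical face on a neutral background.

    Deterministic for a fixed seed: the only randomness is mild per-pixel
    skin texture noise (sd 2 gray levels).
    """
    if side_px < MIN_SIDE:
        raise InvalidSizeError(f"side_px must be >= {MIN_SIDE}, got {side_px}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cx, cy = 0.5 * side_px, 0.52 * side_px
    a, b = 0.33 * side_px, 0.42 * side_px
    yy, xx = np.mgrid[0:side_px, 0:side_px]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    img = np.empty((side_px, side_px, 3), dtype=np.float64)
    img[:] = BACKGROUND
    noise = rng.normal(0.0, 2.0, size=(side_px, side_px, 1))
    img[mask] = (np.array(skin_tone, dtype=float) + noise)[mask]
    return FaceCanvas(
        image=np.clip(img, 0, 255).astype(np.uint8),
        mask=mask,
        skin_tone=tuple(skin_tone),
        center=(cx, cy),
        axes=(a, b),
    )


# ---------------------------------------------------------------------------
# placement


def _iou_xywh(a, b) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    return inter / (aw * ah + bw * bh - inter)


def _coverage(inner, outer) -> float:
    """Fraction of ``inner``'s area covered by ``outer``."""
    ix = max(0.0, min(inner[0] + inner[2], outer[0] + outer[2]) - max(inner[0], outer[0]))
    iy = max(0.0, min(inner[1] + inner[3], outer[1] + outer[3]) - max(inner[1], outer[1]))
    return (ix * iy) / (inner[2] * inner[3])


def sample_lesions(
    counts: dict[str, int],
    canvas: FaceCanvas,
    layout: LayoutConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[LesionAnnotation]:
    """Place exactly the requested number of lesions per category.

    Centers are drawn from a mixture of the category's facial-zone prior
    (weight ``zone_weight``) and a face-uniform component. Placements that
    exceed the same-category IoU cap, mutually cover another lesion beyond
    ``max_coverage`` (which would paint it over), or stick out of the image
    are rejected and redrawn; persistent failure raises
    :class:`PlacementError` naming the category.
    """
    layout = layout or LayoutConfig()
    counts = normalize_counts(counts)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    side = canvas.side
    scale = side / _BASE_SIDE

    face_idx = np.flatnonzero(canvas.mask.ravel())
    zone_idx: dict[str, np.ndarray] = {}
    for cat, zones in ZONE_PRIOR.items():
        if zones is not None and counts[cat] > 0:
            m = np.zeros_like(canvas.mask)
            for z in zones:
                m |= canvas.zone_mask(z)
            zone_idx[cat] = np.flatnonzero(m.ravel())

    placed: list[LesionAnnotation] = []
    for cat in CATEGORIES:
        n = counts[cat]
        if n == 0:
            continue
        spec = RENDER_SPEC[cat]
        same_boxes = []
        for k in range(n):
            ok = False
            for _ in range(layout.max_attempts):
                r = max(1.0, spec["r"] * scale) * rng.uniform(0.85, 1.2)
                rx = r * spec.get("aspect", 1.0)
                ry = r
                use_zone = cat in zone_idx and rng.random() < layout.zone_weight
                pool = zone_idx[cat] if use_zone else face_idx
                flat = int(pool[rng.integers(len(pool))])
                cy, cx = divmod(flat, side)
                bbox = (cx - rx, cy - ry, 2 * rx, 2 * ry)
                if bbox[0] < 0 or bbox[1] < 0 or bbox[0] + bbox[2] > side or bbox[1] + bbox[3] > side:
                    continue
                if any(_iou_xywh(bbox, b) > layout.max_iou_same for b in same_boxes):
                    continue
                if any(
                    _coverage(a.bbox, bbox) > layout.max_coverage
                    or _coverage(bbox, a.bbox) > layout.max_coverage
                    for a in placed
                ):
                    continue
                ok = True
                break
            if not ok:
                raise PlacementError(cat, n, k)
            same_boxes.append(bbox)
            placed.append(LesionAnnotation(category=cat, bbox=bbox, score=1.0))
    return placed


# ---------------------------------------------------------------------------
# rendering


def render_lesions(
    canvas: FaceCanvas,
    annotations: list[LesionAnnotation],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw lesions onto a copy of the canvas image, in annotation order.

    Each lesion gets a small uniform color jitter (+-5 per channel) shared
    by all its pixels; shapes are hard-edged ellipses except melasma, which
    is alpha-blended to look diffuse.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    img = canvas.image.astype(np.float64).copy()
    side = canvas.side
    yy, xx = np.mgrid[0:side, 0:side]
    for a in annotations:
        spec = RENDER_SPEC[a.category]
        x, y, w, h = a.bbox
        cx, cy = x + w / 2.0, y + h / 2.0
        rx, ry = w / 2.0, h / 2.0
        d2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
        color = np.array(spec["color"], dtype=float) + rng.uniform(-5, 5, size=3)
        style = spec["style"]
        if style == "disc":
            img[d2 <= 1.0] = color
        elif style == "pustule":
            img[d2 <= 1.0] = color
            core = np.array(spec["core_color"], dtype=float) + rng.uniform(-3, 3, size=3)
            img[d2 <= spec["core_frac"] ** 2] = core
        elif style == "ring":
            img[(d2 <= 1.0) & (d2 >= spec["ring_frac"] ** 2)] = color
        elif style == "blend":
            m = d2 <= 1.0
            alpha = spec["alpha"]
            img[m] = alpha * color + (1.0 - alpha) * img[m]
        else:  # pragma: no cover
            raise ValueError(f"unknown render style {style!r}")
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# severity generation


def severity_from_counts(
    counts: dict[str, int],
    rule: GradingRuleConfig = DEFAULT_RULE,
    jitter_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> int:
    """Draw a severity grade consistent with the count-interval prior.

    The grade is the interval midpoint (ties round half down) plus rounded
    Gaussian jitter, clamped into the interval, so the generated grade is
    always inside ``counts_to_interval(counts)``.
    """
    interval = counts_to_interval(counts, rule)
    g = interval.midpoint
    if jitter_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        g = int(g + np.floor(rng.normal(0.0, jitter_sd) + 0.5))
    return int(min(max(g, interval.lo), interval.hi))


@dataclass
class SyntheticSubject:
    """One generated patient: image, ground truth lesions, counts, grade."""

    subject_id: int
    image: np.ndarray
    annotations: list[LesionAnnotation]
    true_counts: dict[str, int]
    true_grade: int
    seed: int

    def __post_init__(self) -> None:
        by_cat = {c: 0 for c in CATEGORIES}
        for a in self.annotations:
            by_cat[a.category] += 1
        assert by_cat == self.true_counts, "annotation/count mismatch"
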