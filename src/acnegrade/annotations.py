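"""Bounding-box lesion annotations and COCO-style JSON I/O.

Boxes follow the COCO convention: ``[x_min, y_min, width, height]`` in
0-based pixel units. Ground-truth annotations carry score 1.0; detections
carry their confidence. Files are written with sorted keys and fixed
separators so identical inputs produce byte-identical JSON.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

from .categories import CATEGORIES, CATEGORY_IDS, ID_TO_CATEGORY
from .errors import InvalidBoxError


@dataclass(frozen=True)
class LesionAnnotation:
    """One lesion (ground truth or detection) on one image."""

    category: str
    bbox: tuple[float, float, float, float]  # x, y, w, h
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidBoxError(f"unknown category {self.category!r}")
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise InvalidBoxError(f"degenerate box w={w}, h={h}")
        if not 0.0 <= self.score <= 1.0:
            raise InvalidBoxError(f"score {self.score} outside [0, 1]")

    @property
    def area(self) -> float:
        return self.bbox[2] * self.bbox[3]

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.bbox
        return x + w / 2.0, y + h / 2.0

    def with_score(self, score: float) -> "LesionAnnotation":
        return replace(self, score=score)


def _coco_categories() -> list[dict]:
    return [
        {"id": CATEGORY_IDS[name], "name": name, "supercategory": "lesion"}
        for name in CATEGORIES
    ]


def write_coco(
    path: str | Path,
    images: list[dict],
    annotations_by_image: dict[int, list[LesionAnnotation]],
    with_scores: bool = False,
) -> None:
    """Write a COCO object-detection JSON file.

    ``images`` entries need id, file_name, width, height. Scores are emitted
    only for detection files (``with_scores=True``).
    """
    anns = []
    ann_id = 1
    for image_id in sorted(annotations_by_image):
        for a in annotations_by_image[image_id]:
            entry = {
                "id": ann_id,
                "image_id": image_id,
                "category_id": CATEGORY_IDS[a.category],
                "bbox": [round(float(v), 3) for v in a.bbox],
                "area": round(float(a.area), 3),
                "iscrowd": 0,
            }
            if with_scores:
                entry["score"] = round(float(a.score), 6)
            anns.append(entry)
            ann_id += 1
    doc = {
        "images": sorted(images, key=lambda im: im["id"]),
        "annotations": anns,
        "categories": _coco_categories(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def read_coco(path: str | Path) -> tuple[list[dict], dict[int, list[LesionAnnotation]]]:
    """Read a COCO JSON file into (images, annotations per image id)."""
    with open(path) as fh:
        doc = json.load(fh)
    id_to_name = {c["id"]: c["name"] for c in doc.get("categories", [])}
    if not id_to_name:
        id_to_name = dict(ID_TO_CATEGORY)
    by_image: dict[int, list[LesionAnnotation]] = {im["id"]: [] for im in doc["images"]}
    for a in doc["annotations"]:
        ann = LesionAnnotation(
            category=id_to_name[a["category_id"]],
            bbox=tuple(float(v) for v in a["bbox"]),
            score=float(a.get("score", 1.0)),
        )
        by_image.setdefault(a["image_id"], []).append(ann)
    return doc["images"], by_image


def write_grades_csv(path: str | Path, grades: dict[int, int]) -> None:
    """CSV with header subject_id,grade."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "grade"])
        for sid in sorted(grades):
            w.writerow([sid, int(grades[sid])])


def read_grades_csv(path: str | Path) -> dict[int, int]:
    out: dict[int, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[int(row["subject_id"])] = int(row["grade"])
    return out


def write_ratings_csv(path: str | Path, ratings: "object") -> None:
    """Long-form ratings CSV (subject_id,rater_id,grade) from a wide DataFrame.

    ``ratings`` is a pandas DataFrame indexed by subject id with one column
    per rater id.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "rater_id", "grade"])
        for sid in ratings.index:
            for rid in ratings.columns:
                w.writerow([sid, rid, int(ratings.loc[sid, rid])])


def read_ratings_csv(path: str | Path):
    """Read a long-form ratings CSV into a wide subjects x raters DataFrame."""
    import pandas as pd

    df = pd.read_csv(path)
    wide = df.pivot(index="subject_id", columns="rater_id", values="grade")
    wide.columns.name = None
    wide.index.name = "subject_id"
    return wide
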