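"""Dataset-level synthesis: subject cohorts, on-disk bundles, rater panels.

A cohort is generated from a severity mix that first samples one band of
the count-to-interval rule uniformly, then samples inflammatory counts
inside that band, then non-inflammatory counts from Poisson rates, and
finally a grade from the interval midpoint with Gaussian jitter. By default
only the seven acne-related categories are produced (melasma and nevus
rates are 0).

Seeding policy: one master seed; subject ``i`` uses
``numpy.random.SeedSequence([master_seed, i])`` so each subject is
independently reproducible regardless of cohort size or generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import annotations as annio
from .categories import CATEGORIES, zero_counts
from .errors import AcnegradeError
from .rule import DEFAULT_RULE, GradingRuleConfig
from .synth import (
    DEFAULT_SKIN_TONE,
    LayoutConfig,
    SyntheticSubject,
    generate_face_canvas,
    render_lesions,
    sample_lesions,
    severity_from_counts,
)

#: (i_range, n_range) per band of the default rule, sampled uniformly.
_DEFAULT_BANDS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((0, 0), (0, 0)),  # -> [1,2]
    ((1, 4), (0, 0)),  # -> [2,3]
    ((5, 14), (0, 0)),  # -> [3,4]
    ((15, 29), (0, 0)),  # -> [4,5]
    ((30, 45), (0, 0)),  # -> [5,6]
    ((0, 30), (1, 1)),  # -> [5,7]
    ((0, 30), (2, 4)),  # -> [6,8]
)

#: Poisson rates for the non-inflammatory categories.
_DEFAULT_RATES: dict[str, float] = {
    "closed_comedone": 4.0,
    "open_comedone": 3.0,
    "atrophic_scar": 2.0,
    "hypertrophic_scar": 0.8,
    "melasma": 0.0,
    "nevus": 0.0,
}


@dataclass
class DatasetConfig:
    """Generation settings for a synthetic cohort."""

    side_px: int = 256
    skin_tone: tuple[int, int, int] = DEFAULT_SKIN_TONE
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    rule: GradingRuleConfig = field(default_factory=lambda: DEFAULT_RULE)
    jitter_sd: float = 0.7
    papule_share: float = 0.7  # papule fraction of the pooled I count
    rates: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RATES))
    train_fraction: float = 0.9


def sample_counts(rng: np.random.Generator, config: DatasetConfig) -> dict[str, int]:
    """Draw one subject's per-category lesion counts from the severity mix."""
    (i_lo, i_hi), (n_lo, n_hi) = _DEFAULT_BANDS[rng.integers(len(_DEFAULT_BANDS))]
    i_count = int(rng.integers(i_lo, i_hi + 1))
    n_count = int(rng.integers(n_lo, n_hi + 1))
    counts = zero_counts()
    counts["papule"] = int(rng.binomial(i_count, config.papule_share))
    counts["pustule"] = i_count - counts["papule"]
    counts["nodule_cyst"] = n_count
    for cat, lam in config.rates.items():
        if lam > 0:
            counts[cat] = int(rng.poisson(lam))
    return counts


def make_subject(
    subject_id: int,
    master_seed: int,
    config: DatasetConfig | None = None,
    counts: dict[str, int] | None = None,
) -> SyntheticSubject:
    """Generate one subject; reproducible from (master_seed, subject_id) alone."""
    config = config or DatasetConfig()
    ss = np.random.SeedSequence([int(master_seed), int(subject_id)])
    r_counts, r_canvas, r_place, r_render, r_grade = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    if counts is None:
        counts = sample_counts(r_counts, config)
    canvas = generate_face_canvas(config.side_px, config.skin_tone, seed=r_canvas)
    anns = sample_lesions(counts, canvas, config.layout, seed=r_place)
    image = render_lesions(canvas, anns, seed=r_render)
    grade = severity_from_counts(counts, config.rule, config.jitter_sd, seed=r_grade)
    return SyntheticSubject(
        subject_id=subject_id,
        image=image,
        annotations=anns,
        true_counts=counts,
        true_grade=grade,
        seed=int(master_seed),
    )


def generate_subjects(
    n_subjects: int,
    master_seed: int,
    config: DatasetConfig | None = None,
) -> list[SyntheticSubject]:
    if n_subjects < 1:
        raise AcnegradeError("n_subjects must be >= 1")
    config = config or DatasetConfig()
    return [make_subject(i, master_seed, config) for i in range(n_subjects)]


def render_dataset(
    out_dir: str | Path,
    n_subjects: int,
    master_seed: int,
    config: DatasetConfig | None = None,
) -> dict:
    """Write a full dataset bundle and return its manifest.

    Layout: ``images/<id>.png``, ``annotations.json`` (COCO), ``grades.csv``,
    ``split.json`` with train/test subject ids (train_fraction, default 9:1,
    assigned by a seeded shuffle).
    """
    config = config or DatasetConfig()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    subjects = generate_subjects(n_subjects, master_seed, config)

    images_meta, anns_by_image, grades = [], {}, {}
    for s in subjects:
        fname = f"{s.subject_id:05d}.png"
        Image.fromarray(s.image).save(out / "images" / fname)
        images_meta.append(
            {
                "id": s.subject_id,
                "file_name": f"images/{fname}",
                "width": s.image.shape[1],
                "height": s.image.shape[0],
            }
        )
        anns_by_image[s.subject_id] = s.annotations
        grades[s.subject_id] = s.true_grade

    annio.write_coco(out / "annotations.json", images_meta, anns_by_image)
    annio.write_grades_csv(out / "grades.csv", grades)

    ids = np.arange(n_subjects)
    np.random.default_rng(np.random.SeedSequence([int(master_seed), 2**20])).shuffle(ids)
    n_train = int(round(config.train_fraction * n_subjects))
    split = {
        "train_ids": sorted(int(i) for i in ids[:n_train]),
        "test_ids": sorted(int(i) for i in ids[n_train:]),
    }
    with open(out / "split.json", "w") as fh:
        json.dump(split, fh, sort_keys=True, separators=(",", ":"))

    manifest = {
        "root": str(out),
        "n_subjects": n_subjects,
        "master_seed": int(master_seed),
        "side_px": config.side_px,
        "images": str(out / "images"),
        "annotations": str(out / "annotations.json"),
        "grades": str(out / "grades.csv"),
        "split": str(out / "split.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# simulated rater panels


@dataclass(frozen=True)
class RaterProfile:
    """A simulated dermatologist: additive bias and Gaussian grade noise."""

    bias: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Default 7-rater panel spanning noise sd 0.2 .. 2.0: a clearly more
#: consistent low-noise triple plus four high-noise raters, emulating a
#: panel from which the three best raters are to be identified.
DEFAULT_PANEL: tuple[RaterProfile, ...] = tuple(
    RaterProfile(bias=0.0, noise_sd=sd) for sd in (0.2, 0.5, 0.8, 1.4, 1.6, 1.8, 2.0)
)


def simulate_raters(
    true_grades: list[int] | np.ndarray,
    profiles: list[RaterProfile] = DEFAULT_PANEL,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a rater panel over subjects with known true grades.

    Rating of rater j on subject s:
    ``clamp(round(true_grade(s) + bias_j + N(0, noise_sd_j)), 1, 8)``
    with plain half-up rounding. Returns a subjects x raters DataFrame with
    rater ids ``R1..Rk``.
    """
    grades = np.asarray(true_grades, dtype=float)
    if grades.size < 2 or len(profiles) < 2:
        raise AcnegradeError("need >= 2 subjects and >= 2 rater profiles")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols = {}
    for j, prof in enumerate(profiles):
        noise = rng.normal(0.0, prof.noise_sd, size=grades.size) if prof.noise_sd > 0 else 0.0
        raw = np.floor(grades + prof.bias + noise + 0.5)
        cols[f"R{j + 1}"] = np.clip(raw, 1, 8).astype(int)
    df = pd.DataFrame(cols, index=pd.RangeIndex(grades.size, name="subject_id"))
    return df
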