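"""End-to-end experiment orchestration.

Stages: generate synthetic cohort -> run the reference detector ->
derive lesion counts and grading intervals -> train/evaluate the grader in
the three fusion modes (unfused, fixed, learnable) -> agreement reports.
Every stage writes its outputs to files under the working directory so
stages are independently inspectable and re-runnable; a manifest records
the config hash, master seed and all artifact paths. Re-running with the
same config and seed reproduces every prediction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .agreement import agreement_report, mean_pairwise_kappa
from .annotations import read_coco, read_grades_csv, write_coco, write_ratings_csv
from .categories import CATEGORIES
from .datasets import DEFAULT_PANEL, DatasetConfig, RaterProfile, render_dataset, simulate_raters
from .detect import DetectorConfig, count_by_category, detect_lesions, evaluate_detection
from .errors import AcnegradeError, LeakageError
from .grader import AcneGrader, GraderConfig, evaluate_grader, train_grader
from .rule import DEFAULT_RULE, GradingRuleConfig, counts_to_interval

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "dataset": {"n_subjects": 60, "side_px": 64, "train_fraction": 0.8, "jitter_sd": 0.7},
    "detector": {"iou_threshold": 0.5, "score_threshold": 0.5},
    "counts_source": "truth",  # truth | detector
    "grader": {"epochs": 20, "resize_side": 64, "input_side": 56, "batch_size": 32},
    "raters": {"noise_sds": [0.2, 0.5, 0.8, 1.1, 1.4, 1.7, 2.0], "k_select": 3},
}

#: quickstart preset: completes in minutes on one CPU
QUICKSTART_CONFIG: dict = {
    "dataset": {"n_subjects": 60, "side_px": 64, "train_fraction": 0.8, "jitter_sd": 0.7},
    "detector": {"iou_threshold": 0.5, "score_threshold": 0.5},
    "counts_source": "truth",
    "grader": {"epochs": 8, "resize_side": 48, "input_side": 40, "batch_size": 32},
    "raters": {"noise_sds": [0.2, 0.5, 0.8, 1.1, 1.4, 1.7, 2.0], "k_select": 3},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    """Hash of the semantically canonicalized config (whitespace-free JSON)."""
    text = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)


def _load_split_images(workdir: Path) -> tuple[dict, dict[int, np.ndarray], dict[int, int], dict]:
    ds = workdir / "dataset"
    images_meta, truths = read_coco(ds / "annotations.json")
    grades = read_grades_csv(ds / "grades.csv")
    with open(ds / "split.json") as fh:
        split = json.load(fh)
    imgs = {}
    for im in images_meta:
        arr = np.asarray(Image.open(ds / im["file_name"]))
        imgs[im["id"]] = arr
    return split, imgs, grades, truths


def run_experiment(config, workdir: str | Path, seed: int = 0) -> dict:
    """Run the staged pipeline and return the experiment manifest.

    The final grading report compares the unfused, fixed-weight and
    learnable-weight kappas on the held-out test split.
    """
    t0 = time.time()
    config = load_config(config)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    stage = "generate"
    try:
        # -- stage 1: generate -----------------------------------------
        dcfg = config["dataset"]
        ds_config = DatasetConfig(
            side_px=int(dcfg["side_px"]),
            train_fraction=float(dcfg["train_fraction"]),
            jitter_sd=float(dcfg["jitter_sd"]),
        )
        render_dataset(workdir / "dataset", int(dcfg["n_subjects"]), seed, ds_config)
        split, imgs, grades, truths = _load_split_images(workdir)
        train_ids, test_ids = split["train_ids"], split["test_ids"]
        if set(train_ids) & set(test_ids):
            raise LeakageError("train/test split overlaps")
        logger.info("stage generate done: %d subjects", len(imgs))

        # -- stage 2: detect + eval-detect -----------------------------
        stage = "detect"
        det_cfg = DetectorConfig()
        results = [detect_lesions(imgs[i], det_cfg, image_id=i) for i in sorted(imgs)]
        write_coco(
            workdir / "detections.json",
            [
                {"id": i, "file_name": f"images/{i:05d}.png", "width": ds_config.side_px, "height": ds_config.side_px}
                for i in sorted(imgs)
            ],
            {r.image_id: r.detections for r in results},
            with_scores=True,
        )
        test_results = [r for r in results if r.image_id in set(test_ids)]
        test_truths = {i: truths[i] for i in test_ids}
        metrics = evaluate_detection(test_results, test_truths, float(config["detector"]["iou_threshold"]))
        _write_json(workdir / "detection_metrics.json", metrics.to_dict())

        # -- stage 3: counts -> intervals ------------------------------
        stage = "intervals"
        source = config["counts_source"]
        rule = DEFAULT_RULE
        counts_by_id: dict[int, dict[str, int]] = {}
        if source == "truth":
            for i in sorted(imgs):
                c = {cat: 0 for cat in CATEGORIES}
                for a in truths[i]:
                    c[a.category] += 1
                counts_by_id[i] = c
        elif source == "detector":
            thr = float(config["detector"]["score_threshold"])
            for r in results:
                counts_by_id[r.image_id] = count_by_category(r, thr)
        else:
            raise AcnegradeError(f"unknown counts_source {source!r}")
        intervals_by_id = {i: counts_to_interval(c, rule) for i, c in counts_by_id.items()}
        _write_json(
            workdir / "intervals.json",
            {str(i): [iv.lo, iv.hi] for i, iv in sorted(intervals_by_id.items())},
        )

        # -- stage 4: train + evaluate graders -------------------------
        stage = "grade-train"
        gcfg = dict(config["grader"])
        base_cfg = GraderConfig(seed=seed, fusion_mode="none", **gcfg)
        tr_imgs = [imgs[i] for i in train_ids]
        tr_grades = [grades[i] for i in train_ids]
        tr_ivs = [intervals_by_id[i] for i in train_ids]
        base = train_grader(tr_imgs, tr_grades, base_cfg)
        base.save(workdir / "grader_base.npz")
        learn_cfg = GraderConfig(seed=seed, fusion_mode="learnable", **gcfg)
        learn = train_grader(
            tr_imgs, tr_grades, learn_cfg, intervals=tr_ivs,
            distinct_intervals=rule.distinct_intervals(),
        )
        learn.save(workdir / "grader_learnable.npz")

        stage = "grade-eval"
        te_imgs = [imgs[i] for i in test_ids]
        te_grades = [grades[i] for i in test_ids]
        te_ivs = [intervals_by_id[i] for i in test_ids]
        reports = {
            "none": evaluate_grader(base, te_imgs, te_grades, test_ids, fusion_mode="none", train_ids=train_ids),
            "fixed": evaluate_grader(base, te_imgs, te_grades, test_ids, intervals=te_ivs, fusion_mode="fixed", train_ids=train_ids),
            "learnable": evaluate_grader(learn, te_imgs, te_grades, test_ids, intervals=te_ivs, fusion_mode="learnable", train_ids=train_ids),
        }
        grading_report = {
            "kappa": {m: r["kappa_linear"] for m, r in reports.items()},
            "reports": reports,
        }
        _write_json(workdir / "grading_report.json", grading_report)

        # -- stage 5: rater panel --------------------------------------
        stage = "agreement"
        rcfg = config["raters"]
        profiles = [RaterProfile(noise_sd=float(sd)) for sd in rcfg["noise_sds"]]
        te_true = [grades[i] for i in test_ids]
        panel = simulate_raters(
            te_true, profiles, seed=np.random.default_rng(np.random.SeedSequence([seed, 0xBEEF]))
        )
        panel.index = pd.Index(test_ids, name="subject_id")
        write_ratings_csv(workdir / "ratings.csv", panel)
        _write_json(workdir / "agreement_report.json", agreement_report(panel, int(rcfg["k_select"])))

        bench = rater_benchmark(panel, {m: r["predictions"] for m, r in reports.items()})
        _write_json(workdir / "rater_benchmark.json", bench)
    except Exception:
        (workdir / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise

    manifest = {
        "tool_version": __version__,
        "config": config,
        "config_hash": chash,
        "master_seed": int(seed),
        "train_ids": train_ids,
        "test_ids": test_ids,
        "outputs": {
            "dataset": str(workdir / "dataset"),
            "detections": str(workdir / "detections.json"),
            "detection_metrics": str(workdir / "detection_metrics.json"),
            "intervals": str(workdir / "intervals.json"),
            "grader_base": str(workdir / "grader_base.npz"),
            "grader_learnable": str(workdir / "grader_learnable.npz"),
            "grading_report": str(workdir / "grading_report.json"),
            "ratings": str(workdir / "ratings.csv"),
            "agreement_report": str(workdir / "agreement_report.json"),
            "rater_benchmark": str(workdir / "rater_benchmark.json"),
        },
        "wall_time_s": round(time.time() - t0, 2),
    }
    _write_json(workdir / "manifest.json", manifest)
    return manifest


def rater_benchmark(panel: pd.DataFrame, ai_predictions: dict[str, list[int]]) -> dict:
    """Append each AI variant as a pseudo-rater and rank by mean pairwise kappa.

    ``panel`` is a subjects x raters rating matrix; each AI prediction list
    must align with the panel's subject index.
    """
    combined = panel.copy()
    for name, preds in ai_predictions.items():
        if len(preds) != len(panel.index):
            raise AcnegradeError(
                f"AI variant {name!r} has {len(preds)} predictions for {len(panel.index)} subjects"
            )
        combined[f"AI_{name}"] = list(preds)
    means = mean_pairwise_kappa(combined)
    ranking = [str(r) for r in means.index]
    return {
        "mean_pairwise_kappa": {str(k): float(v) for k, v in means.items()},
        "ranking": ranking,
        "ai_ranks": {
            f"AI_{name}": ranking.index(f"AI_{name}") + 1 for name in ai_predictions
        },
        "n_raters": int(combined.shape[1]),
    }
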