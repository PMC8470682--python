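"""Experiment orchestration: folds, configuration, and the two-arm protocol.

``run_experiment`` reproduces the study design end to end on synthetic
scenes: generate a frame set with ground truth, split it, train the
detector and the classifier separately on the color arm and on the
grayscale arm, score detection by the center-point criterion (image-level
accuracy over polyp frames, specificity over normal frames, exact 95%
CIs), score classification (confusion matrix, metric family, AUC, NPV),
compare the two arms with the exact McNemar test on their paired
per-frame outcomes, and stratify detection by lesion pixel area at the
1600 and 1800 px thresholds.  Everything derives from one seed; rerunning
a config reproduces the report bit for bit, and every report embeds its
config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation as ev
from .classifier import ClassifierConfig, classify, predict_proba, train_classifier
from .detector import DetectorConfig, detect, train_detector
from .imaging import BBox, rgb_to_grayscale
from .synthetic import DatasetBundle, generate_dataset


@dataclass(frozen=True)
class FoldPlan:
    """Balanced k-fold partition of item indices; reproducible from seed."""

    k: int
    assignment: tuple[int, ...]
    seed: int

    def fold(self, i: int) -> list[int]:
        return [j for j, f in enumerate(self.assignment) if f == i]

    @property
    def folds(self) -> list[list[int]]:
        return [self.fold(i) for i in range(self.k)]


def make_folds(n_items: int, k: int = 5, seed: int = 0) -> FoldPlan:
    """Random balanced partition into k folds (sizes differ by at most 1)."""
    if n_items < k:
        raise ValueError(f"cannot split {n_items} items into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    assignment = np.empty(n_items, dtype=int)
    for pos, item in enumerate(order):
        assignment[item] = pos % k
    return FoldPlan(k=k, assignment=tuple(int(a) for a in assignment), seed=seed)


@dataclass
class RunConfig:
    """Everything a two-arm synthetic experiment needs.

    Cutoff defaults are the operating points of the reference system (0.2
    detection objectness, 0.5 classification softmax).  Training epochs
    and the classifier's crop-based reduced input are desk-scale choices;
    the architectures themselves are fixed.
    """

    n_images: int = 400
    negatives_fraction: float = 0.25
    class_mix: float = 0.5
    palette_mix: float = 0.5
    area_range: tuple[float, float] = (800.0, 6400.0)
    width: int = 640
    height: int = 480
    arms: tuple[str, ...] = ("color", "grayscale")
    grayscale_mode: str = "standard"
    detector_cutoff: float = 0.2
    classifier_cutoff: float = 0.5
    detector_epochs: int = 8
    classifier_epochs: int = 5
    detector_batch: int = 16
    classifier_batch: int = 8
    lr: float = 1e-3
    train_fraction: float = 0.75
    classifier_input_hw: tuple[int, int] = (192, 256)
    crop_margin: float = 0.2
    seed: int = 0

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("area_range", "arms", "classifier_input_hw"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def crop_lesion(img: np.ndarray, box: BBox, margin: float) -> np.ndarray:
    """Cut the lesion region with a relative margin, clamped to the frame."""
    h, w = img.shape[:2]
    mx, my = int(round(margin * box.width)), int(round(margin * box.height))
    x0, x1 = max(0, box.x_min - mx), min(w, box.x_max + mx)
    y0, y1 = max(0, box.y_min - my), min(h, box.y_max + my)
    return img[y0:y1, x0:x1]


def _arm_image(img: np.ndarray, arm: str, grayscale_mode: str) -> np.ndarray:
    if arm == "grayscale":
        return rgb_to_grayscale(img, mode=grayscale_mode)
    return img


def _split(bundle: DatasetBundle, train_fraction: float, seed: int):
    """Stratified (polyp vs normal) train/test index split."""
    rng = np.random.default_rng(seed)
    polyp = [i for i, r in enumerate(bundle.records) if r.gt_boxes]
    normal = [i for i, r in enumerate(bundle.records) if not r.gt_boxes]
    train: list[int] = []
    test: list[int] = []
    for group in (polyp, normal):
        order = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        train += [group[j] for j in order[:n_train]]
        test += [group[j] for j in order[n_train:]]
    return sorted(train), sorted(test)


def _evaluate_detection(model, bundle, idx, config, arm) -> dict:
    """Per-frame center-point outcomes on the given index set."""
    polyp_ok: list[bool] = []
    normal_ok: list[bool] = []
    per_frame: dict[str, bool] = {}
    for i in idx:
        rec = bundle.records[i]
        img = _arm_image(bundle.images[i], arm, config.grayscale_mode)
        dets = detect(img, model, cutoff=config.detector_cutoff, grayscale_mode=config.grayscale_mode)
        if rec.gt_boxes:
            outcome = ev.match_by_center([d.box for d in dets], rec.gt_boxes)
            polyp_ok.append(outcome.image_correct)
            per_frame[rec.image_path] = outcome.image_correct
        else:
            normal_ok.append(len(dets) == 0)
    acc = ev.image_level_accuracy(polyp_ok) if polyp_ok else float("nan")
    res = {
        "n_polyp_frames": len(polyp_ok),
        "n_detected": int(sum(polyp_ok)),
        "detection_accuracy_pct": round(acc, 2),
        "per_frame": per_frame,
    }
    if polyp_ok:
        res["detection_accuracy_ci_pct"] = ev.binomial_ci(sum(polyp_ok), len(polyp_ok))
    if normal_ok:
        res["n_normal_frames"] = len(normal_ok)
        res["normal_specificity_pct"] = round(ev.image_level_accuracy(normal_ok), 2)
    return res


def _evaluate_classification(model, bundle, idx, config, arm) -> dict:
    y_true: list[int] = []
    scores: list[float] = []
    for i in idx:
        rec = bundle.records[i]
        if not rec.gt_boxes:
            continue
        img = _arm_image(bundle.images[i], arm, config.grayscale_mode)
        box = max(rec.gt_boxes, key=lambda b: b.area)
        crop = crop_lesion(img, box, config.crop_margin)
        decision = classify(
            crop,
            model,
            cutoff=config.classifier_cutoff,
            grayscale_mode=config.grayscale_mode,
            input_hw=config.classifier_input_hw,
        )
        y_true.append(1 if rec.class_label == "neoplastic" else 0)
        scores.append(decision.p_neoplastic)
    y_pred = [1 if s >= config.classifier_cutoff else 0 for s in scores]
    cm = ev.ConfusionMatrix2x2.from_labels(y_true, y_pred)
    out = {
        "n": len(y_true),
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "metrics_pct": ev.compute_metrics(cm).as_dict(),
        "accuracy_pct": round(100.0 * (cm.tp + cm.tn) / cm.total, 2),
    }
    if len(set(y_true)) == 2:
        out["auc"] = round(ev.roc_auc(scores, y_true), 4)
    if cm.tn + cm.fn > 0:
        out["npv_pct"] = ev.npv(cm)
    return out


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full two-arm protocol; returns (and optionally writes) the report."""
    bundle = generate_dataset(
        config.n_images,
        seed=config.seed,
        negatives_fraction=config.negatives_fraction,
        class_mix=config.class_mix,
        palette_mix=config.palette_mix,
        area_range=config.area_range,
        width=config.width,
        height=config.height,
    )
    train_idx, test_idx = _split(bundle, config.train_fraction, config.seed + 1)

    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_train": len(train_idx),
        "n_test": len(test_idx),
        "arms": {},
    }

    for arm in config.arms:
        in_channels = 3 if arm == "color" else 1
        det_cfg = DetectorConfig(
            in_channels=in_channels,
            epochs=config.detector_epochs,
            batch_size=config.detector_batch,
            lr=config.lr,
            cutoff=config.detector_cutoff,
            grayscale_mode=config.grayscale_mode,
        )
        train_set = [
            (_arm_image(bundle.images[i], arm, config.grayscale_mode), bundle.records[i].gt_boxes)
            for i in train_idx
        ]
        det_model, det_log = train_detector(train_set, det_cfg, seed=config.seed + 11)
        det_eval = _evaluate_detection(det_model, bundle, test_idx, config, arm)

        clf_cfg = ClassifierConfig(
            in_channels=in_channels,
            epochs=config.classifier_epochs,
            batch_size=config.classifier_batch,
            lr=config.lr,
            cutoff=config.classifier_cutoff,
            input_hw=config.classifier_input_hw,
            grayscale_mode=config.grayscale_mode,
        )
        clf_train = [
            (
                crop_lesion(
                    _arm_image(bundle.images[i], arm, config.grayscale_mode),
                    max(bundle.records[i].gt_boxes, key=lambda b: b.area),
                    config.crop_margin,
                ),
                bundle.records[i].class_label,
            )
            for i in train_idx
            if bundle.records[i].gt_boxes
        ]
        clf_model, clf_log = train_classifier(clf_train, clf_cfg, seed=config.seed + 13)
        clf_eval = _evaluate_classification(clf_model, bundle, test_idx, config, arm)

        report["arms"][arm] = {
            "detection": det_eval,
            "classification": clf_eval,
            "detector_log": det_log,
            "classifier_log": clf_log,
        }

    if len(config.arms) == 2:
        a, b = config.arms
        frames = sorted(report["arms"][a]["detection"]["per_frame"])
        va = [report["arms"][a]["detection"]["per_frame"][f] for f in frames]
        vb = [report["arms"][b]["detection"]["per_frame"][f] for f in frames]
        table = ev.paired_table(va, vb)
        report["paired_comparison"] = {
            "arms": [a, b],
            "both": table.both,
            "only_" + a: table.only_a,
            "only_" + b: table.only_b,
            "neither": table.neither,
            "mcnemar_p": table.mcnemar_p,
        }

    # size stratification of grayscale-arm detection at the two thresholds
    strata = {}
    ref_arm = config.arms[-1]
    per_frame = report["arms"][ref_arm]["detection"]["per_frame"]
    polyp_recs = [bundle.records[i] for i in test_idx if bundle.records[i].gt_boxes]
    for thr in (1600, 1800):
        below, above = ev.stratify_by_area(polyp_recs, thr)
        entry = {}
        for name, recs in (("below", below), ("at_or_above", above)):
            oks = [per_frame[r.image_path] for r in recs]
            entry[name] = {
                "n": len(oks),
                "accuracy_pct": round(ev.image_level_accuracy(oks), 2) if oks else None,
            }
        strata[str(thr)] = entry
    report["size_strata"] = {"arm": ref_arm, "thresholds": strata}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
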