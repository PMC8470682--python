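"""Evaluation protocol and paired statistics for polyp detection/classification.

Detection is scored by the MICCAI-2015 endoscopic-vision-challenge
center-point criterion: a predicted box is a true positive iff its center
falls inside (edges inclusive) some ground-truth box.  There is no true
negative at box level because every polyp frame contains at least one
lesion; image-level accuracy is simply the fraction of polyp frames with a
correct detection.  Classification of neoplastic (positive) versus
hyperplastic polyps is summarised by a 2x2 confusion matrix and the
accuracy / precision / recall / F1 / F2 family, plus the negative
predictive value that decides the ASGE diagnose-and-leave threshold
(NPV >= 90%).

Paired comparisons of two detection arms on the same frames use the exact
(binomial) McNemar test — the discordant counts here are far too small for
the chi-square approximation — and proportions carry Clopper-Pearson exact
95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .imaging import AnnotatedImage, BBox


@dataclass(frozen=True)
class DetectionOutcome:
    """Box-level counts for one image (no TN by design)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def image_correct(self) -> bool:
        """At least one prediction hit a ground-truth box."""
        return self.tp > 0


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Neoplastic-positive confusion counts: tp, fn, fp, tn."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionMatrix2x2":
        """Labels are 1 = neoplastic, 0 = hyperplastic."""
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("label vectors differ in length")
        return cls(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Percentages rounded to 1 decimal; NaN marks an undefined metric."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    f2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "f2": self.f2,
        }


@dataclass(frozen=True)
class PairedOutcomeTable:
    """Cross-tabulation of per-image success for two arms on the same frames."""

    both: int
    only_a: int
    only_b: int
    neither: int

    @property
    def n(self) -> int:
        return self.both + self.only_a + self.only_b + self.neither

    @property
    def mcnemar_p(self) -> float:
        return mcnemar_exact(self.only_a, self.only_b)


def match_by_center(
    pred_boxes: Sequence[BBox],
    gt_boxes: Sequence[BBox],
    fn_mode: str = "image",
) -> DetectionOutcome:
    """Score predictions against ground truth by the center-point criterion.

    TP: predictions whose center lies inside (edge-inclusive) some GT box.
    FP: predictions whose center lies in no GT box.
    FN (``fn_mode="image"``, the reference protocol): one false negative
    iff the frame has ground truth but no prediction box appears at all.
    ``fn_mode="per_gt"`` instead counts every GT box not hit by any
    prediction center — useful for multi-polyp frames.
    """
    if fn_mode not in ("image", "per_gt"):
        raise ValueError("fn_mode must be 'image' or 'per_gt'")
    tp = fp = 0
    hit = [False] * len(gt_boxes)
    for pred in pred_boxes:
        cx, cy = pred.center
        inside = False
        for i, gt in enumerate(gt_boxes):
            if gt.contains_point(cx, cy):
                inside = True
                hit[i] = True
        if inside:
            tp += 1
        else:
            fp += 1
    if fn_mode == "image":
        fn = 1 if (gt_boxes and not pred_boxes) else 0
    else:
        fn = sum(1 for h in hit if not h)
    return DetectionOutcome(tp=tp, fp=fp, fn=fn)


def image_level_accuracy(
    detected: int | Sequence[bool], total: int | None = None
) -> float:
    """Percentage of polyp frames with a correct detection (full precision).

    Accepts either (count_detected, count_total) or a per-image boolean
    sequence.  For normal frames "correct" means zero boxes emitted; the
    caller supplies the booleans accordingly.
    """
    if total is None:
        seq = list(detected)  # type: ignore[arg-type]
        n_det, n_tot = sum(bool(x) for x in seq), len(seq)
    else:
        n_det, n_tot = int(detected), int(total)  # type: ignore[arg-type]
    if n_tot <= 0:
        raise ValueError("total must be positive")
    if not 0 <= n_det <= n_tot:
        raise ValueError("detected count outside [0, total]")
    return 100.0 * n_det / n_tot


def compute_metrics(cm: ConfusionMatrix2x2) -> MetricsReport:
    """Accuracy, precision, recall, F1 and F2 as 1-decimal percentages.

    Acc = (TP+TN)/total, Prec = TP/(TP+FP), Rec = TP/(TP+FN),
    F1 = 2PR/(P+R), F2 = 5PR/(4P+R).  A zero denominator yields NaN for
    that metric rather than an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    acc = ratio(cm.tp + cm.tn, cm.total)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    rec = ratio(cm.tp, cm.tp + cm.fn)
    f1 = ratio(2 * prec * rec, prec + rec)
    f2 = ratio(5 * prec * rec, 4 * prec + rec)
    r1 = lambda v: round(100.0 * v, 1) if np.isfinite(v) else float("nan")
    return MetricsReport(r1(acc), r1(prec), r1(rec), r1(f1), r1(f2))


def npv(cm: ConfusionMatrix2x2, decimals: int = 0) -> float:
    """Negative predictive value TN/(TN+FN), as a percentage.

    Rounded to the integer percent by default, matching how clinical NPV
    figures are quoted against the 90% diagnose-and-leave threshold.
    """
    den = cm.tn + cm.fn
    if den == 0:
        raise ValueError("NPV undefined: TN + FN = 0")
    return round(100.0 * cm.tn / den, decimals)


def mcnemar_exact(only_a: int, only_b: int) -> float:
    """Two-sided exact McNemar p-value on discordant pair counts.

    Under the null the discordants split Binomial(n, 1/2);
    p = min(1, 2 * P(X <= min(a, b))).  With no discordant pairs p = 1.
    """
    if only_a < 0 or only_b < 0:
        raise ValueError("discordant counts must be non-negative")
    n = only_a + only_b
    if n == 0:
        return 1.0
    k = min(only_a, only_b)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))


def binomial_ci(
    successes: int,
    n: int,
    level: float = 0.95,
    method: str = "clopper-pearson",
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI as 1-decimal percentages.

    ``method="wilson"`` selects the Wilson score interval instead.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes outside [0, n]")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}[method]
    low, high = proportion_confint(successes, n, alpha=1.0 - level, method=sm_method)
    return (round(100.0 * low, 1), round(100.0 * high, 1))


def paired_table(
    outcomes_a: Sequence[bool], outcomes_b: Sequence[bool]
) -> PairedOutcomeTable:
    """Cross-tabulate per-image success of two arms over the same frames."""
    a = [bool(x) for x in outcomes_a]
    b = [bool(x) for x in outcomes_b]
    if len(a) != len(b):
        raise ValueError("outcome vectors differ in length")
    pairs = list(zip(a, b))
    return PairedOutcomeTable(
        both=sum(1 for x, y in pairs if x and y),
        only_a=sum(1 for x, y in pairs if x and not y),
        only_b=sum(1 for x, y in pairs if y and not x),
        neither=sum(1 for x, y in pairs if not x and not y),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank statistic, ties averaged).

    ``labels`` are 1 = neoplastic, 0 = hyperplastic; ``scores`` are the
    predicted neoplastic probabilities.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, s))


def stratify_by_area(
    records: Iterable[AnnotatedImage], threshold_px: int
) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    """Split records at GT-box pixel area: (below, at_or_above).

    A record goes to the "below" stratum iff its largest GT box has area
    strictly less than ``threshold_px`` (a 40x40 = 1600 px lesion sits in
    the at-or-above stratum of the 1600 threshold).  Records without any
    GT box are rejected.
    """
    below: list[AnnotatedImage] = []
    at_or_above: list[AnnotatedImage] = []
    for rec in records:
        if not rec.gt_boxes:
            raise ValueError(f"record {rec.image_path} has no GT boxes")
        area = max(box.area for box in rec.gt_boxes)
        (below if area < threshold_px else at_or_above).append(rec)
    return below, at_or_above
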