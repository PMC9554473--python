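"""Detection and counting evaluation metrics.

Covers confusion-count accuracy/recall, average precision (101-point
interpolated area under the precision-recall curve, plus the mAP@0.5:0.95
average over IoU thresholds), and the counting errors RMSE / MAE together
with the relative mean error / mean accuracy pair used to report per-image
spike-count agreement.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .boxes import box_iou_matrix

__all__ = ["ConfusionCounts", "CountSeries", "accuracy", "recall",
           "average_precision", "mean_average_precision_range", "rmse",
           "mae", "mean_error_accuracy", "match_detections",
           "write_count_report"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class CountSeries:
    """Paired per-image predicted (p) and ground-truth (q) object counts."""

    predicted: np.ndarray
    ground_truth: np.ndarray
    image_ids: list[str] | None = None

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=np.float64)
        self.ground_truth = np.asarray(self.ground_truth, dtype=np.float64)
        if self.predicted.shape != self.ground_truth.shape:
            raise ValueError("predicted and ground-truth counts differ in length")
        if self.predicted.size == 0:
            raise ValueError("count series must contain at least one image")

    def __len__(self) -> int:
        return self.predicted.size


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN) / (TP+FN+FP+TN)."""
    denom = c.tp + c.fn + c.fp + c.tn
    if denom == 0:
        raise ValueError("accuracy undefined for all-zero confusion counts")
    return (c.tp + c.tn) / denom


def recall(c: ConfusionCounts) -> float:
    """TP / (TP+FN)."""
    if c.tp + c.fn == 0:
        raise ValueError("recall undefined when TP+FN = 0")
    return c.tp / (c.tp + c.fn)


def rmse(s: CountSeries) -> float:
    """Root-mean-square per-image count error."""
    return float(np.sqrt(np.mean((s.predicted - s.ground_truth) ** 2)))


def mae(s: CountSeries) -> float:
    """Mean absolute per-image count error; never exceeds the RMSE."""
    return float(np.mean(np.abs(s.predicted - s.ground_truth)))


def mean_error_accuracy(s: CountSeries) -> tuple[float, float]:
    """Mean relative count error and its complement, both in percent.

    mean_error = 100 * mean(|p_i - q_i| / q_i); mean_accuracy =
    100 - mean_error, floored at zero.  Requires every q_i > 0.
    """
    if np.any(s.ground_truth <= 0):
        raise ValueError("mean_error_accuracy requires positive ground-truth counts")
    err = 100.0 * float(np.mean(np.abs(s.predicted - s.ground_truth)
                                / s.ground_truth))
    return err, max(0.0, 100.0 - err)


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------


def match_detections(dets_by_image: dict, gts_by_image: dict,
                     iou_match: float = 0.5):
    """Greedily match score-ranked detections to ground truths.

    ``dets_by_image`` maps image id -> (boxes (N,4) xyxy, scores (N,));
    ``gts_by_image`` maps image id -> boxes (M,4).  Each ground truth is
    matched at most once.  Returns (scores, tp_flags, n_gt) over all images,
    globally sorted by descending score.
    """
    all_scores, all_tp = [], []
    n_gt = 0
    for img_id, gt in gts_by_image.items():
        gt = np.asarray(gt, dtype=np.float64).reshape(-1, 4)
        n_gt += len(gt)
        boxes, scores = dets_by_image.get(img_id, (np.zeros((0, 4)), np.zeros(0)))
        boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
        scores = np.asarray(scores, dtype=np.float64).reshape(-1)
        order = np.argsort(-scores, kind="stable")
        used = np.zeros(len(gt), dtype=bool)
        tp = np.zeros(len(order), dtype=bool)
        if len(gt) and len(order):
            ious = box_iou_matrix(boxes[order], gt)
            for r in range(len(order)):
                cand = np.where(~used & (ious[r] >= iou_match))[0]
                if cand.size:
                    best = cand[np.argmax(ious[r][cand])]
                    used[best] = True
                    tp[r] = True
        all_scores.append(scores[order])
        all_tp.append(tp)
    for img_id, (boxes, scores) in dets_by_image.items():
        if img_id not in gts_by_image:
            scores = np.asarray(scores, dtype=np.float64).reshape(-1)
            all_scores.append(np.sort(scores)[::-1])
            all_tp.append(np.zeros(len(scores), dtype=bool))
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    tp = np.concatenate(all_tp) if all_tp else np.zeros(0, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    return scores[order], tp[order], n_gt


def average_precision(dets_by_image: dict, gts_by_image: dict,
                      iou_match: float = 0.5) -> float:
    """101-point interpolated area under the precision-recall curve."""
    scores, tp, n_gt = match_detections(dets_by_image, gts_by_image, iou_match)
    if n_gt == 0:
        raise ValueError("average precision undefined with zero ground truths")
    if len(scores) == 0:
        return 0.0
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(~tp)
    rec = tp_cum / n_gt
    prec = tp_cum / (tp_cum + fp_cum)
    # precision envelope, then mean precision at 101 recall levels
    mrec = np.concatenate(([0.0], rec, [1.0]))
    mpre = np.concatenate(([1.0], prec, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    levels = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(mrec, levels, side="left")
    return float(np.mean(mpre[idx]))


def mean_average_precision_range(dets_by_image: dict, gts_by_image: dict,
                                 lo: float = 0.5, hi: float = 0.95,
                                 step: float = 0.05) -> float:
    """Mean AP over IoU thresholds lo:step:hi (the mAP@0.5:0.95 protocol)."""
    thresholds = np.arange(lo, hi + 1e-9, step)
    return float(np.mean([average_precision(dets_by_image, gts_by_image, t)
                          for t in thresholds]))


# ---------------------------------------------------------------------------
# Report writer
# ---------------------------------------------------------------------------


def write_count_report(out_dir, series: CountSeries, summary: dict) -> None:
    """Write a per-image CSV and a summary JSON for a counting run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = series.image_ids or [str(i) for i in range(len(series))]
    with open(out_dir / "per_image.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "predicted", "ground_truth", "error"])
        for img_id, p, q in zip(ids, series.predicted, series.ground_truth):
            writer.writerow([img_id, int(p), int(q), int(p - q)])
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
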