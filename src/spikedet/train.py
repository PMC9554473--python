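"""Training, counting and evaluation pipeline.

Trains the detector with stochastic gradient descent (initial learning rate
0.01, momentum 0.937, weight decay 0.0005, batch size 8, 60 epochs, 640 px
inputs by default), gated by the best-possible-recall anchor check: anchors
are refit by k-means only when the default priors cover less than 98% of
the labeled boxes under the size-ratio rule.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import (AnchorSet, LabeledImage, best_possible_recall, fit_anchors,
                   letterbox, mosaic, unletterbox_boxes)
from .loss import LossWeights, detection_loss
from .metrics import (CountSeries, average_precision, mae,
                      mean_average_precision_range, mean_error_accuracy,
                      match_detections, rmse, write_count_report)
from .model import (DEFAULT_ANCHORS, Model, ModelConfig, decode_and_nms,
                    load_checkpoint, save_checkpoint)
from .nn import SGD, Tensor

__all__ = ["TrainConfig", "train", "detect_images", "count", "evaluate",
           "check_anchors"]

BPR_THRESHOLD = 0.98


@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 8
    lr0: float = 0.01
    lrf: float = 0.01            # final lr fraction (cosine decay floor)
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: int = 3
    imgsz: int = 640
    mosaic_prob: float = 1.0
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.lr0 < 0 \
                or self.imgsz % 32:
            raise ValueError("invalid training configuration")

    def lr_at(self, epoch: int) -> float:
        """Warm-up then cosine decay from lr0 to lrf*lr0."""
        if self.warmup_epochs and epoch < self.warmup_epochs:
            return self.lr0 * (epoch + 1) / self.warmup_epochs
        span = max(self.epochs - self.warmup_epochs, 1)
        t = (epoch - self.warmup_epochs) / span
        return self.lr0 * (self.lrf + (1 - self.lrf)
                           * 0.5 * (1 + math.cos(math.pi * t)))


def check_anchors(items: list[LabeledImage], anchors=DEFAULT_ANCHORS,
                  imgsz: int = 640, rng_seed: int = 0, log=print):
    """The best-possible-recall gate: keep anchors at BPR >= 0.98, else refit.

    Box sizes are measured after letterbox scaling to the training
    resolution.
    """
    wh = []
    for item in items:
        h, w = item.shape
        s = min(imgsz / w, imgsz / h)
        b = item.boxes
        if len(b):
            wh.append(np.column_stack([(b[:, 2] - b[:, 0]) * s,
                                       (b[:, 3] - b[:, 1]) * s]))
    if not wh:
        raise ValueError("dataset has no labeled boxes")
    wh = np.concatenate(wh)
    flat = np.asarray(anchors, dtype=np.float64).reshape(-1, 2)
    bpr = best_possible_recall(wh, flat)
    if bpr >= BPR_THRESHOLD:
        log(f"anchors kept: best possible recall {bpr:.4f} >= {BPR_THRESHOLD}")
        return anchors, bpr, False
    log(f"anchors refit: best possible recall {bpr:.4f} < {BPR_THRESHOLD}")
    fitted = fit_anchors(wh, k=len(flat), rng_seed=rng_seed, default=flat)
    return fitted.grouped(), best_possible_recall(wh, fitted), True


def _prepare_batch(items, imgsz):
    """Letterbox to a square training canvas; returns images + pixel targets."""
    imgs, targets = [], []
    for item in items:
        padded, s, pad = letterbox(item.image, imgsz, square=True)
        imgs.append(padded.astype(np.float32).transpose(2, 0, 1) / 255.0)
        if len(item.boxes):
            b = item.boxes * s
            b[:, 0::2] += pad[0]
            b[:, 1::2] += pad[1]
            t = np.column_stack([(b[:, 0] + b[:, 2]) / 2,
                                 (b[:, 1] + b[:, 3]) / 2,
                                 b[:, 2] - b[:, 0], b[:, 3] - b[:, 1],
                                 item.classes])
        else:
            t = np.zeros((0, 5), dtype=np.float32)
        targets.append(t)
    return np.stack(imgs), targets


def train(items: list[LabeledImage], cfg: TrainConfig | None = None,
          out_dir=None, model_cfg: ModelConfig | None = None, log=print):
    """Train the detector; returns (model, per-epoch history).

    Checkpoints (last + best by total loss) are written to ``out_dir`` when
    given, with a JSONL log of per-epoch loss components.
    """
    cfg = cfg or TrainConfig()
    if not items:
        raise ValueError("empty dataset")
    anchors, bpr, refit = check_anchors(items, imgsz=cfg.imgsz,
                                        rng_seed=cfg.seed, log=log)
    model_cfg = model_cfg or ModelConfig()
    model_cfg.anchors = tuple(tuple(tuple(a) for a in s) for s in anchors)
    model_cfg.input_size = cfg.imgsz
    model_cfg.seed = cfg.seed
    model = Model(model_cfg)

    decay, no_decay = [], []
    for name, p in model.named_parameters():
        (no_decay if p.data.ndim <= 1 else decay).append(p)
    opt = SGD([{"params": decay, "weight_decay": cfg.weight_decay},
               {"params": no_decay, "weight_decay": 0.0}],
              lr=cfg.lr0, momentum=cfg.momentum)

    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    history = []
    best_loss = np.inf
    model.train()
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(len(items))
        sums = np.zeros(4)
        n_batches = 0
        t0 = time.time()
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch_items = []
            for j in idx:
                if cfg.mosaic_prob > 0 and rng.random() < cfg.mosaic_prob:
                    picks = [items[j]] + [items[int(rng.integers(len(items)))]
                                          for _ in range(3)]
                    seed = int(rng.integers(2 ** 31 - 1))
                    batch_items.append(mosaic(picks, canvas=cfg.imgsz,
                                              rng_seed=seed))
                else:
                    batch_items.append(items[j])
            images, targets = _prepare_batch(batch_items, cfg.imgsz)
            outputs = model(Tensor(images))
            total, box, obj, cls = detection_loss(
                outputs, targets, model_cfg.anchors, model_cfg.strides,
                cfg.loss_weights)
            opt.zero_grad()
            total.backward()
            opt.step()
            sums += [total.item(), box.item(), obj.item(), cls.item()]
            n_batches += 1
        means = sums / max(n_batches, 1)
        record = {"epoch": epoch, "lr": opt.lr, "loss": means[0],
                  "box": means[1], "obj": means[2], "cls": means[3],
                  "seconds": time.time() - t0}
        history.append(record)
        log(f"epoch {epoch:3d}  lr {opt.lr:.5f}  loss {means[0]:.4f}  "
            f"box {means[1]:.4f}  obj {means[2]:.4f}  cls {means[3]:.4f}")
        if out_dir is not None:
            with open(out_dir / "train_log.jsonl", "a") as fh:
                fh.write(json.dumps(record) + "\n")
            save_checkpoint(out_dir / "last.npz", model,
                            extra={"epoch": epoch, "bpr": bpr})
            if means[0] < best_loss:
                best_loss = means[0]
                save_checkpoint(out_dir / "best.npz", model,
                                extra={"epoch": epoch, "bpr": bpr})
    return model, history


# ---------------------------------------------------------------------------
# Inference / counting / evaluation
# ---------------------------------------------------------------------------


def detect_images(model: Model, items: list[LabeledImage],
                  conf: float = 0.25, iou: float = 0.45):
    """Run the detector; returns per-image detections in original pixels."""
    model.eval()
    cfg = model.cfg
    results = {}
    for item in items:
        padded, s, pad = letterbox(item.image, cfg.input_size, square=True)
        x = padded.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
        outputs = model(Tensor(x))
        dets = decode_and_nms(outputs, conf, iou, cfg.anchors, cfg.strides,
                              image_shape=padded.shape[:2])[0]
        if dets:
            boxes = unletterbox_boxes(np.stack([d[0] for d in dets]), s, pad)
            h, w = item.shape
            boxes[:, 0::2] = boxes[:, 0::2].clip(0, w)
            boxes[:, 1::2] = boxes[:, 1::2].clip(0, h)
            scores = np.array([d[1] for d in dets])
        else:
            boxes = np.zeros((0, 4))
            scores = np.zeros(0)
        results[item.source_id] = (boxes, scores)
    return results


def count(items: list[LabeledImage], model: Model | None = None,
          checkpoint=None, conf: float = 0.25, iou: float = 0.45,
          detections=None, out_dir=None) -> dict:
    """Count spikes per image and score against labeled ground truth.

    ``detections`` may inject precomputed per-image (boxes, scores) —
    e.g. a ground-truth-echo stub — instead of running the model.
    """
    if detections is None:
        if model is None:
            if checkpoint is None:
                raise ValueError("need a model, checkpoint or detections")
            model, _ = load_checkpoint(checkpoint)
        detections = detect_images(model, items, conf, iou)
    ids = [it.source_id for it in items]
    p = np.array([len(detections[i][0]) for i in ids], dtype=float)
    q = np.array([len(it.boxes) for it in items], dtype=float)
    series = CountSeries(p, q, image_ids=ids)
    summary = {"n_images": len(items),
               "rmse": rmse(series), "mae": mae(series)}
    if np.all(q > 0):
        err, acc = mean_error_accuracy(series)
        summary["mean_error_pct"] = err
        summary["mean_accuracy_pct"] = acc
    gts = {it.source_id: it.boxes for it in items}
    if any(len(b) for b in gts.values()):
        summary.update(evaluate(detections, gts))
    if out_dir is not None:
        write_count_report(out_dir, series, summary)
    return summary


def evaluate(detections: dict, ground_truth: dict,
             iou_match: float = 0.5) -> dict:
    """Detection metrics: recall at the match threshold, mAP@0.5, mAP@0.5:0.95.

    ``detections``: image id -> (boxes, scores); ``ground_truth``: image id
    -> boxes.  Image id sets must agree.
    """
    missing = sorted(set(ground_truth) ^ set(detections))
    if missing:
        raise ValueError(f"image id mismatch between detections and ground "
                         f"truth: {missing}")
    _, tp, n_gt = match_detections(detections, ground_truth, iou_match)
    return {
        "recall": float(tp.sum() / n_gt) if n_gt else 0.0,
        "map50": average_precision(detections, ground_truth, iou_match),
        "map50_95": mean_average_precision_range(detections, ground_truth),
    }
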