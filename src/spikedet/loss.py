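"""Composite detection training loss.

Localization uses the CIoU loss between decoded predictions and their
matched targets; objectness and class terms are binary cross-entropy.
Targets are matched to anchors by the size-ratio rule
``max(wh_t/wh_a, wh_a/wh_t) < 4`` and assigned to the grid cell containing
the box center.  Objectness targets at matched cells are the pair's CIoU
similarity clamped to [0, 1]; the equilibrium weight alpha of the CIoU
aspect term is excluded from gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import Tensor, bce_with_logits, maximum, minimum

__all__ = ["LossWeights", "ciou_tensor", "match_targets", "detection_loss"]


@dataclass(frozen=True)
class LossWeights:
    box: float = 0.05
    obj: float = 1.0
    cls: float = 0.5


def ciou_tensor(pred_xywh: Tensor, gt_xywh: np.ndarray) -> Tensor:
    """CIoU similarity of (M, 4) center-size boxes, differentiable in pred."""
    gt = np.asarray(gt_xywh, dtype=np.float32)
    px, py = pred_xywh[:, 0], pred_xywh[:, 1]
    pw, ph = pred_xywh[:, 2], pred_xywh[:, 3]
    gx, gy, gw, gh = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]

    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    gx1, gx2 = gx - gw * 0.5, gx + gw * 0.5
    gy1, gy2 = gy - gh * 0.5, gy + gh * 0.5

    iw = minimum(px2, gx2) - maximum(px1, gx1)
    ih = minimum(py2, gy2) - maximum(py1, gy1)
    inter = iw.clip(0, None) * ih.clip(0, None)
    union = pw * ph + gw * gh - inter
    iou = inter / (union + 1e-9)

    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    cw = maximum(px2, gx2) - minimum(px1, gx1)
    ch = maximum(py2, gy2) - minimum(py1, gy1)
    c2 = cw ** 2 + ch ** 2 + 1e-9

    v = (4.0 / math.pi ** 2) * ((pred_xywh[:, 2] / pred_xywh[:, 3]).arctan()
                                - np.arctan(gw / gh)) ** 2
    # alpha is a stop-gradient constant
    alpha = v.data / ((1.0 - iou.data) + v.data + 1e-9)
    return iou - rho2 / c2 - Tensor(alpha) * v


def match_targets(targets, anchors, strides, grid_shapes, ratio_thresh=4.0):
    """Assign labeled boxes to (image, scale, anchor, cell) slots.

    ``targets``: per-image arrays of (cx, cy, w, h[, class]) in input pixels.
    Returns per scale: index arrays (img, anchor, gy, gx), target xywh in
    pixels and target class ids.
    """
    anchors = np.asarray(anchors, dtype=np.float32)
    out = []
    for s, stride in enumerate(strides):
        h, w = grid_shapes[s]
        idx_img, idx_a, idx_gy, idx_gx, txywh, tcls = [], [], [], [], [], []
        for bi, t in enumerate(targets):
            t = np.asarray(t, dtype=np.float32)
            if t.size == 0:
                continue
            t = t.reshape(len(t), -1)
            for row in t:
                cx, cy, bw, bh = row[:4]
                cls = int(row[4]) if len(row) > 4 else 0
                gx = min(int(cx / stride), w - 1)
                gy = min(int(cy / stride), h - 1)
                for ai in range(anchors.shape[1]):
                    aw, ah = anchors[s, ai]
                    r = max(bw / aw, aw / bw, bh / ah, ah / bh)
                    if r < ratio_thresh:
                        idx_img.append(bi)
                        idx_a.append(ai)
                        idx_gy.append(gy)
                        idx_gx.append(gx)
                        txywh.append((cx, cy, bw, bh))
                        tcls.append(cls)
        out.append((np.asarray(idx_img, dtype=int), np.asarray(idx_a, dtype=int),
                    np.asarray(idx_gy, dtype=int), np.asarray(idx_gx, dtype=int),
                    np.asarray(txywh, dtype=np.float32).reshape(-1, 4),
                    np.asarray(tcls, dtype=int)))
    return out


def detection_loss(outputs, targets, anchors, strides=(8, 16, 32),
                   weights: LossWeights | None = None):
    """Total training loss and its (box, obj, cls) components.

    ``outputs``: list of per-scale raw head tensors (B, 3, H, W, 5+nc);
    ``targets``: list (length B) of per-image (N, 5) arrays
    (cx, cy, w, h, class) in input pixels.
    """
    weights = weights or LossWeights()
    anchors = np.asarray(anchors, dtype=np.float32)
    grid_shapes = [o.shape[2:4] for o in outputs]
    matches = match_targets(targets, anchors, strides, grid_shapes)

    zero = Tensor(np.float32(0.0))
    box_loss, cls_loss, obj_loss = zero, zero, zero
    n_box_terms = 0
    for s, out in enumerate(outputs):
        img_i, a_i, gy, gx, txywh, tcls = matches[s]
        stride = strides[s]
        b, na, h, w, no = out.shape
        nc = no - 5
        obj_target = np.zeros((b, na, h, w), dtype=np.float32)
        if len(img_i):
            p = out[img_i, a_i, gy, gx]          # (M, 5+nc)
            pxy = (p[:, 0:2].sigmoid() * 2.0 - 0.5
                   + np.stack([gx, gy], axis=1).astype(np.float32)) * float(stride)
            pwh = (p[:, 2:4].sigmoid() * 2.0) ** 2 * anchors[s][a_i]
            from .nn import concat
            pred_xywh = concat([pxy, pwh], axis=1)
            ciou = ciou_tensor(pred_xywh, txywh)
            box_loss = box_loss + (1.0 - ciou).mean() * len(img_i)
            n_box_terms += len(img_i)
            obj_target[img_i, a_i, gy, gx] = np.clip(ciou.data, 0.0, 1.0)
            if nc > 0:
                cls_target = np.zeros((len(img_i), nc), dtype=np.float32)
                cls_target[np.arange(len(img_i)), tcls] = 1.0
                cls_loss = cls_loss + bce_with_logits(p[:, 5:], cls_target)
        obj_loss = obj_loss + bce_with_logits(out[..., 4], obj_target)
    if n_box_terms:
        box_loss = box_loss * (1.0 / n_box_terms)
    cls_loss = cls_loss * (1.0 / len(outputs))
    obj_loss = obj_loss * (1.0 / len(outputs))
    total = weights.box * box_loss + weights.obj * obj_loss + weights.cls * cls_loss
    return total, box_loss, obj_loss, cls_loss
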