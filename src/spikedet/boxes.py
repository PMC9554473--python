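"""Axis-aligned bounding boxes, IoU and the complete-IoU (CIoU) loss.

The CIoU loss between a predicted box and a ground-truth box is

    L = 1 - IoU + rho^2 / c^2 + alpha * v

where ``rho^2`` is the squared distance between box centers, ``c^2`` the
squared diagonal of the smallest axis-aligned box enclosing both, ``v``
measures aspect-ratio inconsistency,

    v = (4 / pi^2) * (arctan(w_gt / h_gt) - arctan(w / h))^2,

and ``alpha = v / ((1 - IoU) + v)`` is an equilibrium weight treated as a
constant with respect to gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BBox", "CiouTerms", "iou", "ciou_loss", "box_iou_matrix"]


@dataclass(frozen=True)
class BBox:
    """A box given by center (cx, cy) and positive size (w, h) in pixels."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box size must be positive, got w={self.w}, h={self.h}")

    @classmethod
    def from_xyxy(cls, x1: float, y1: float, x2: float, y2: float) -> "BBox":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    @property
    def x1(self) -> float:
        return self.cx - self.w / 2

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2

    @property
    def xyxy(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class CiouTerms:
    """Decomposition of one CIoU evaluation."""

    iou: float
    rho2: float   # squared center distance
    c2: float     # squared enclosing-box diagonal
    v: float      # aspect-ratio inconsistency
    alpha: float  # equilibrium weight (constant w.r.t. gradients)

    @property
    def loss(self) -> float:
        return 1.0 - self.iou + self.rho2 / self.c2 + self.alpha * self.v


def iou(a: BBox, b: BBox) -> float:
    """Intersection area over union area; symmetric, in [0, 1].

    Areas are derived from the same corner coordinates as the intersection
    so that identical boxes give exactly 1.
    """
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    inter = max(iw, 0.0) * max(ih, 0.0)
    area_a = (a.x2 - a.x1) * (a.y2 - a.y1)
    area_b = (b.x2 - b.x1) * (b.y2 - b.y1)
    union = area_a + area_b - inter
    return inter / union


def ciou_loss(pred: BBox, gt: BBox) -> tuple[float, CiouTerms]:
    """CIoU loss and its term decomposition; zero iff the boxes coincide."""
    i = iou(pred, gt)
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    cw = max(pred.x2, gt.x2) - min(pred.x1, gt.x1)
    ch = max(pred.y2, gt.y2) - min(pred.y1, gt.y1)
    c2 = cw * cw + ch * ch
    v = (4.0 / math.pi ** 2) * (
        math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = 0.0 if v == 0 else v / ((1.0 - i) + v)
    terms = CiouTerms(iou=i, rho2=rho2, c2=c2, v=v, alpha=alpha)
    return terms.loss, terms


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of xyxy arrays, shapes (N, 4) and (M, 4) -> (N, M)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.clip(br - tl, 0, None).prod(axis=2)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)
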