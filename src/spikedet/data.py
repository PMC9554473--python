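"""Dataset handling: annotation I/O, preprocessing and augmentation.

Implements the three training-time preprocessing procedures of the detector
(mosaic composition of four images, adaptive anchor fitting gated on the
best-possible-recall rule, and aspect-preserving letterbox scaling with
minimal stride-aligned padding), plus sliding-window tiling of large field
images and readers/writers for Pascal VOC XML and YOLO normalized-txt
annotations.

All internal coordinates are 0-based, half-open pixel coordinates
(x1 <= x < x2); the VOC convention (1-based inclusive corners) and the YOLO
convention (normalized center/size) are applied only at the file boundary.
"""

from __future__ import annotations

import hashlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["LabeledImage", "AnchorSet", "letterbox", "unletterbox_boxes",
           "mosaic", "tile_image", "best_possible_recall", "fit_anchors",
           "read_voc_xml", "write_voc_xml", "read_yolo_txt", "write_yolo_txt",
           "load_dataset"]


@dataclass
class LabeledImage:
    """An RGB image with class-tagged boxes (xyxy pixels, half-open)."""

    image: np.ndarray                       # (H, W, 3) uint8
    boxes: np.ndarray                       # (N, 4) float xyxy
    classes: np.ndarray                     # (N,) int
    source_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.classes = np.asarray(self.classes, dtype=int).reshape(-1)
        if len(self.boxes) != len(self.classes):
            raise ValueError("boxes and classes differ in length")
        h, w = self.image.shape[:2]
        if len(self.boxes):
            if (self.boxes[:, 0] < -1e-6).any() or (self.boxes[:, 1] < -1e-6).any() \
                    or (self.boxes[:, 2] > w + 1e-6).any() \
                    or (self.boxes[:, 3] > h + 1e-6).any():
                raise ValueError("boxes must lie within image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    def xywh_boxes(self) -> np.ndarray:
        """Boxes as (cx, cy, w, h)."""
        b = self.boxes
        return np.column_stack([(b[:, 0] + b[:, 2]) / 2, (b[:, 1] + b[:, 3]) / 2,
                                b[:, 2] - b[:, 0], b[:, 3] - b[:, 1]])


@dataclass
class AnchorSet:
    """Nine (w, h) anchor priors grouped three per scale by ascending area."""

    wh: np.ndarray  # (9, 2)

    def __post_init__(self):
        self.wh = np.asarray(self.wh, dtype=np.float64).reshape(-1, 2)
        if (self.wh <= 0).any():
            raise ValueError("anchor sizes must be positive")
        order = np.argsort(self.wh.prod(axis=1), kind="stable")
        self.wh = self.wh[order]

    def grouped(self) -> tuple:
        k = len(self.wh) // 3
        return tuple(tuple(map(tuple, self.wh[i * k:(i + 1) * k]))
                     for i in range(3))


# ---------------------------------------------------------------------------
# Letterbox (adaptive image scaling)
# ---------------------------------------------------------------------------


def letterbox(img: np.ndarray, target: int = 640, stride: int = 32,
              pad_value: int = 114, square: bool = False):
    """Aspect-preserving resize with the fewest stride-aligned padded pixels.

    Returns (padded image, scale, (left, top, right, bottom) padding).  With
    ``square=True`` both output dimensions are padded to ``target`` (fixed
    training shape); otherwise each is padded only to the next multiple of
    ``stride``.
    """
    h, w = img.shape[:2]
    scale = min(target / w, target / h)
    nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
    if (nw, nh) != (w, h):
        resized = np.asarray(
            Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
    else:
        resized = img
    if square:
        pw, ph = target, target
    else:
        pw = int(np.ceil(nw / stride) * stride)
        ph = int(np.ceil(nh / stride) * stride)
    left = (pw - nw) // 2
    top = (ph - nh) // 2
    right = pw - nw - left
    bottom = ph - nh - top
    out = np.full((ph, pw) + img.shape[2:], pad_value, dtype=img.dtype)
    out[top:top + nh, left:left + nw] = resized
    return out, scale, (left, top, right, bottom)


def unletterbox_boxes(boxes: np.ndarray, scale: float, pad) -> np.ndarray:
    """Map xyxy boxes from letterboxed back to original image coordinates."""
    left, top = pad[0], pad[1]
    out = np.asarray(boxes, dtype=np.float64).copy()
    out[:, 0::2] = (out[:, 0::2] - left) / scale
    out[:, 1::2] = (out[:, 1::2] - top) / scale
    return out


# ---------------------------------------------------------------------------
# Mosaic augmentation
# ---------------------------------------------------------------------------


def mosaic(items, canvas: int = 640, rng_seed: int = 0,
           min_visibility: float = 0.25, pad_value: int = 114) -> LabeledImage:
    """Stitch four labeled images into one canvas around a random center.

    Each source is randomly rescaled (jitter U(0.5, 1.5) on top of the
    fit-to-canvas scale) and placed into one quadrant of a 2x working
    canvas around a center sampled uniformly from its middle half; the
    output is the canvas-sized crop around that center.  Boxes are remapped,
    clipped, and dropped when less than ``min_visibility`` of their original
    area survives.  Deterministic given ``rng_seed``.
    """
    if len(items) != 4:
        raise ValueError(f"mosaic needs exactly 4 images, got {len(items)}")
    rng = np.random.default_rng(rng_seed)
    c = canvas
    work = np.full((2 * c, 2 * c, 3), pad_value, dtype=np.uint8)
    xc = int(rng.integers(c // 2, c + c // 2 + 1))
    yc = int(rng.integers(c // 2, c + c // 2 + 1))
    boxes_out, classes_out = [], []
    for quad, item in enumerate(items):
        h, w = item.shape
        s = float(rng.uniform(0.5, 1.5)) * c / max(h, w)
        nw, nh = max(1, round(w * s)), max(1, round(h * s))
        img = np.asarray(Image.fromarray(item.image).resize((nw, nh),
                                                            Image.BILINEAR))
        if quad == 0:    # top-left of center
            x1, y1 = max(xc - nw, 0), max(yc - nh, 0)
            x2, y2 = xc, yc
        elif quad == 1:  # top-right
            x1, y1 = xc, max(yc - nh, 0)
            x2, y2 = min(xc + nw, 2 * c), yc
        elif quad == 2:  # bottom-left
            x1, y1 = max(xc - nw, 0), yc
            x2, y2 = xc, min(yc + nh, 2 * c)
        else:            # bottom-right
            x1, y1 = xc, yc
            x2, y2 = min(xc + nw, 2 * c), min(yc + nh, 2 * c)
        # source window anchored at the center corner
        sx1 = nw - (x2 - x1) if quad in (0, 2) else 0
        sy1 = nh - (y2 - y1) if quad in (0, 1) else 0
        work[y1:y2, x1:x2] = img[sy1:sy1 + (y2 - y1), sx1:sx1 + (x2 - x1)]
        if len(item.boxes):
            b = item.boxes * s
            b[:, 0::2] += x1 - sx1
            b[:, 1::2] += y1 - sy1
            orig_area = (item.boxes[:, 2] - item.boxes[:, 0]) \
                * (item.boxes[:, 3] - item.boxes[:, 1]) * s * s
            boxes_out.append(np.column_stack([b, orig_area]))
            classes_out.append(item.classes)
    # canvas-sized crop centered on the mosaic center, kept inside the work area
    ox = min(max(xc - c // 2, 0), c)
    oy = min(max(yc - c // 2, 0), c)
    out_img = work[oy:oy + c, ox:ox + c]
    if boxes_out:
        b = np.concatenate(boxes_out)
        cls = np.concatenate(classes_out)
        orig_area = b[:, 4]
        b = b[:, :4]
        b[:, 0::2] -= ox
        b[:, 1::2] -= oy
        clipped = b.copy()
        clipped[:, 0::2] = clipped[:, 0::2].clip(0, c)
        clipped[:, 1::2] = clipped[:, 1::2].clip(0, c)
        area = (clipped[:, 2] - clipped[:, 0]).clip(0) \
            * (clipped[:, 3] - clipped[:, 1]).clip(0)
        keep = area >= min_visibility * orig_area
        keep &= area > 0
        b, cls = clipped[keep], cls[keep]
    else:
        b = np.zeros((0, 4))
        cls = np.zeros(0, dtype=int)
    return LabeledImage(out_img, b, cls, source_id=f"mosaic-{rng_seed}")


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


def tile_image(item: LabeledImage, tile: int = 640, stride: int = 320,
               min_visibility: float = 0.3) -> list[LabeledImage]:
    """Sliding-window tiles covering the image, last window border-snapped."""
    h, w = item.shape
    if h < tile or w < tile:
        pad_h, pad_w = max(tile - h, 0), max(tile - w, 0)
        img = np.pad(item.image, ((0, pad_h), (0, pad_w), (0, 0)))
        item = LabeledImage(img, item.boxes, item.classes, item.source_id)
        h, w = item.shape

    def starts(dim):
        xs = list(range(0, dim - tile + 1, stride))
        if xs[-1] != dim - tile:
            xs.append(dim - tile)
        return xs

    tiles = []
    for y0 in starts(h):
        for x0 in starts(w):
            crop = item.image[y0:y0 + tile, x0:x0 + tile]
            if len(item.boxes):
                b = item.boxes.copy()
                b[:, 0::2] -= x0
                b[:, 1::2] -= y0
                clipped = b.copy()
                clipped[:, 0::2] = clipped[:, 0::2].clip(0, tile)
                clipped[:, 1::2] = clipped[:, 1::2].clip(0, tile)
                area = (clipped[:, 2] - clipped[:, 0]).clip(0) \
                    * (clipped[:, 3] - clipped[:, 1]).clip(0)
                orig = (item.boxes[:, 2] - item.boxes[:, 0]) \
                    * (item.boxes[:, 3] - item.boxes[:, 1])
                keep = area >= min_visibility * orig
                bb, cc = clipped[keep], item.classes[keep]
            else:
                bb = np.zeros((0, 4))
                cc = np.zeros(0, dtype=int)
            tiles.append(LabeledImage(crop, bb, cc,
                                      source_id=f"{item.source_id}@{x0},{y0}"))
    return tiles


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------


def best_possible_recall(boxes_wh, anchors, ratio_thresh: float = 4.0) -> float:
    """Fraction of boxes matchable by some anchor under the size-ratio rule.

    A box (w, h) matches an anchor (aw, ah) when
    ``max(w/aw, aw/w, h/ah, ah/h) < ratio_thresh``.
    """
    wh = np.asarray(boxes_wh, dtype=np.float64).reshape(-1, 2)
    if len(wh) == 0:
        raise ValueError("best_possible_recall requires at least one box")
    a = anchors.wh if isinstance(anchors, AnchorSet) else \
        np.asarray(anchors, dtype=np.float64).reshape(-1, 2)
    r = wh[:, None, :] / a[None, :, :]
    worst = np.maximum(r, 1.0 / r).max(axis=2)      # (N, K)
    return float((worst.min(axis=1) < ratio_thresh).mean())


def fit_anchors(boxes_wh, k: int = 9, rng_seed: int = 0,
                default=None, ratio_thresh: float = 4.0) -> AnchorSet:
    """Seeded k-means over box sizes (whitened w, h) -> k anchors.

    The fitted anchors are returned only if their best possible recall on the
    same boxes is at least that of ``default`` (when given); otherwise the
    default set is kept.
    """
    from sklearn.cluster import KMeans

    wh = np.asarray(boxes_wh, dtype=np.float64).reshape(-1, 2)
    if len(wh) < k:
        raise ValueError(f"need at least {k} boxes to fit {k} anchors, "
                         f"got {len(wh)}")
    std = wh.std(axis=0)
    std[std < 1e-9] = 1.0
    km = KMeans(n_clusters=k, n_init=10, random_state=rng_seed)
    km.fit(wh / std)
    centers = km.cluster_centers_ * std
    fitted = AnchorSet(centers)
    if default is not None:
        default = default if isinstance(default, AnchorSet) else AnchorSet(
            np.asarray(default, dtype=np.float64).reshape(-1, 2))
        if best_possible_recall(wh, fitted, ratio_thresh) < \
                best_possible_recall(wh, default, ratio_thresh):
            return default
    return fitted


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

_CLASS_NAMES = ("spike",)


def _num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:.6f}"


def write_voc_xml(path, item: LabeledImage,
                  class_names=_CLASS_NAMES) -> None:
    """Write Pascal VOC XML (1-based inclusive corner coordinates)."""
    h, w = item.shape
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = item.source_id or Path(path).stem
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "3"
    for box, cls in zip(item.boxes, item.classes):
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = class_names[cls]
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = _num(box[0] + 1)
        ET.SubElement(bnd, "ymin").text = _num(box[1] + 1)
        ET.SubElement(bnd, "xmax").text = _num(box[2])
        ET.SubElement(bnd, "ymax").text = _num(box[3])
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def read_voc_xml(path, image: np.ndarray | None = None,
                 class_names=_CLASS_NAMES) -> LabeledImage:
    """Read Pascal VOC XML; pairs with ``image`` or a placeholder canvas."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML {path}: {exc}") from exc

    def _req(el, tag):
        child = el.find(tag)
        if child is None or child.text is None:
            raise ValueError(f"VOC XML {path}: missing element <{tag}>")
        return child.text

    size = root.find("size")
    if size is None:
        raise ValueError(f"VOC XML {path}: missing element <size>")
    w = int(_req(size, "width"))
    h = int(_req(size, "height"))
    boxes, classes = [], []
    for obj in root.iter("object"):
        name = _req(obj, "name")
        if name not in class_names:
            raise ValueError(f"VOC XML {path}: unknown class <name> {name!r}")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"VOC XML {path}: <object> missing <bndbox>")
        x1 = float(_req(bnd, "xmin")) - 1
        y1 = float(_req(bnd, "ymin")) - 1
        x2 = float(_req(bnd, "xmax"))
        y2 = float(_req(bnd, "ymax"))
        boxes.append((x1, y1, x2, y2))
        classes.append(class_names.index(name))
    if image is None:
        image = np.zeros((h, w, 3), dtype=np.uint8)
    return LabeledImage(image, np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
                        classes, source_id=root.findtext("filename", ""))


def write_yolo_txt(path, item: LabeledImage) -> None:
    """One line per box: ``class cx cy w h`` normalized to [0, 1]."""
    h, w = item.shape
    lines = []
    for box, cls in zip(item.boxes, item.classes):
        cx = (box[0] + box[2]) / 2 / w
        cy = (box[1] + box[3]) / 2 / h
        bw = (box[2] - box[0]) / w
        bh = (box[3] - box[1]) / h
        lines.append(f"{cls} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path, image: np.ndarray) -> LabeledImage:
    """Read YOLO txt labels for ``image`` (needed for denormalization)."""
    h, w = image.shape[:2]
    boxes, classes = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, "
                             f"got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, bw, bh = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparsable number") from exc
        boxes.append(((cx - bw / 2) * w, (cy - bh / 2) * h,
                      (cx + bw / 2) * w, (cy + bh / 2) * h))
        classes.append(cls)
    return LabeledImage(image, np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
                        classes, source_id=Path(path).stem)


def load_dataset(root) -> list[LabeledImage]:
    """Load an ``images/`` + ``labels/`` (YOLO txt) directory pair."""
    root = Path(root)
    items = []
    for img_path in sorted((root / "images").iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        image = np.asarray(Image.open(img_path).convert("RGB"))
        label = root / "labels" / (img_path.stem + ".txt")
        if label.exists():
            item = read_yolo_txt(label, image)
        else:
            item = LabeledImage(image, np.zeros((0, 4)), np.zeros(0, dtype=int))
        item.source_id = img_path.stem
        items.append(item)
    if not items:
        raise ValueError(f"no images found under {root / 'images'}")
    return items


def file_md5(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()
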