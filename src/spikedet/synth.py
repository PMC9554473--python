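"""Synthetic wheat-field scene generator with exact ground truth.

Renders elongated, randomly oriented elliptical "spikes" with awn-like
strokes and a grain-row texture over a textured canopy background, and
emits one tight bounding box per spike.  The generator controls the three
factors that make real field imagery hard: spike density, mutual
occlusion/overlap, and spike-background color similarity (a green-on-green
mode versus a green-on-yellow contrast mode).  Everything is deterministic
per seed, so the generator doubles as the test fixture factory for the rest
of the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .data import LabeledImage, file_md5, write_voc_xml, write_yolo_txt

__all__ = ["SceneSpec", "generate_scene", "generate_dataset",
           "realized_overlap_fraction"]


@dataclass
class SceneSpec:
    """Parameters of one rendered scene."""

    canvas: tuple[int, int] = (640, 640)        # (H, W)
    n_spikes: int = 40
    length_range: tuple[float, float] = (40.0, 90.0)   # major axis, px
    width_range: tuple[float, float] = (12.0, 22.0)    # minor axis, px
    orientation_range: tuple[float, float] = (0.0, 180.0)  # degrees
    overlap_target: float = 0.3   # fraction of spikes intersecting another
    background: str = "green_similar"  # or "yellow_contrast"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be non-negative")
        if not 0.0 <= self.overlap_target <= 1.0:
            raise ValueError("overlap_target must lie in [0, 1]")
        if self.background not in ("green_similar", "yellow_contrast"):
            raise ValueError(f"unknown background mode {self.background!r}")
        margin = self.length_range[1] / 2 + 8
        if min(self.canvas) <= 2 * margin and self.n_spikes > 0:
            raise ValueError(
                f"canvas {self.canvas} too small for spikes up to "
                f"{self.length_range[1]} px")


_BG_COLORS = {
    "green_similar": (62, 108, 52),
    "yellow_contrast": (168, 152, 74),
}
_SPIKE_COLOR = (96, 132, 62)  # greenish spike


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.canvas
    base = np.asarray(_BG_COLORS[spec.background], dtype=np.float64)
    img = np.tile(base, (h, w, 1))
    # low-frequency illumination + leaf-like streak texture
    low = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=24)
    streak = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)),
                                     sigma=(14, 2))
    tex = 26.0 * low / (np.abs(low).max() + 1e-9) \
        + 14.0 * streak / (np.abs(streak).max() + 1e-9)
    img += tex[..., None] * np.array([0.8, 1.0, 0.7])
    img += rng.normal(0, 4, (h, w, 3))
    return img


def _render_spike(img: np.ndarray, rng: np.random.Generator,
                  cy: float, cx: float, length: float, width: float,
                  angle_deg: float) -> tuple[float, float, float, float]:
    """Draw one spike; returns its tight xyxy box from the rendered mask."""
    h, w = img.shape[:2]
    a, b = length / 2, width / 2
    theta = np.deg2rad(angle_deg)
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
    mask[rr, cc] = True
    # grain-row texture: brightness modulated along the major axis
    yy, xx = rr.astype(np.float64), cc.astype(np.float64)
    axial = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    lateral = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    rows = 18.0 * np.cos(axial * (2 * np.pi / 7.0)) \
        + 10.0 * np.cos(lateral * (2 * np.pi / max(width / 2.2, 3.0)))
    color = np.asarray(_SPIKE_COLOR, dtype=np.float64) \
        + rng.normal(0, 6, 3)
    img[rr, cc] = color + rows[:, None] * np.array([0.9, 1.0, 0.6])
    # awns: a few short strokes fanning out from the spike tip
    tip_y = cy + a * np.cos(theta)
    tip_x = cx + a * np.sin(theta)
    n_awns = int(rng.integers(3, 7))
    for _ in range(n_awns):
        ang = theta + rng.normal(0, 0.35)
        ln = rng.uniform(4, 12)
        ey = int(round(np.clip(tip_y + ln * np.cos(ang), 0, h - 1)))
        ex = int(round(np.clip(tip_x + ln * np.sin(ang), 0, w - 1)))
        rr2, cc2 = draw_line(int(round(np.clip(tip_y, 0, h - 1))),
                             int(round(np.clip(tip_x, 0, w - 1))), ey, ex)
        mask[rr2, cc2] = True
        img[rr2, cc2] = color * 0.85
    ys, xs = np.nonzero(mask)
    return float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1)


def _boxes_intersect(a, b) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def generate_scene(spec: SceneSpec) -> LabeledImage:
    """Render one scene; same spec (incl. seed) -> byte-identical output."""
    rng = np.random.default_rng(spec.rng_seed)
    img = _background(spec, rng)
    h, w = spec.canvas
    margin = spec.length_range[1] / 2 + 8
    n = spec.n_spikes
    n_overlapped = round(n * spec.overlap_target)
    n_pairs = (n_overlapped + 1) // 2

    placements: list[tuple[float, float, float, float, float]] = []
    planned_boxes: list[tuple[float, float, float, float]] = []

    def sample_geom():
        return (rng.uniform(*spec.length_range), rng.uniform(*spec.width_range),
                rng.uniform(*spec.orientation_range))

    def approx_box(cy, cx, length, width, ang_deg):
        # orientation-aware AABB of the ellipse, major axis padded by the
        # awn reach
        a = length / 2 + 12
        b = width / 2 + 2
        th = np.deg2rad(ang_deg)
        ey = np.hypot(a * np.cos(th), b * np.sin(th))
        ex = np.hypot(a * np.sin(th), b * np.cos(th))
        return (cx - ex, cy - ey, cx + ex, cy + ey)

    placed = 0
    # overlapped pairs first: a base spike plus a partner offset so their
    # extents intersect
    for _ in range(n_pairs):
        if placed >= n:
            break
        length, width, ang = sample_geom()
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        placements.append((cy, cx, length, width, ang))
        planned_boxes.append(approx_box(cy, cx, length, width, ang))
        placed += 1
        if placed >= n:
            break
        l2, w2, a2 = sample_geom()
        off = rng.uniform(0.25, 0.6) * (length + l2) / 2
        dirang = rng.uniform(0, 2 * np.pi)
        cy2 = float(np.clip(cy + off * np.cos(dirang), margin, h - margin))
        cx2 = float(np.clip(cx + off * np.sin(dirang), margin, w - margin))
        placements.append((cy2, cx2, l2, w2, a2))
        planned_boxes.append(approx_box(cy2, cx2, l2, w2, a2))
        placed += 1
    # the rest: rejection-sampled to avoid intersection where possible
    while placed < n:
        length, width, ang = sample_geom()
        for _ in range(120):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            cand = approx_box(cy, cx, length, width, ang)
            if not any(_boxes_intersect(cand, p) for p in planned_boxes):
                break
        placements.append((cy, cx, length, width, ang))
        planned_boxes.append(approx_box(cy, cx, length, width, ang))
        placed += 1

    boxes = []
    for cy, cx, length, width, ang in placements:
        boxes.append(_render_spike(img, rng, cy, cx, length, width, ang))
    img = np.clip(img, 0, 255).astype(np.uint8)
    boxes_arr = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    boxes_arr[:, 0::2] = boxes_arr[:, 0::2].clip(0, w)
    boxes_arr[:, 1::2] = boxes_arr[:, 1::2].clip(0, h)
    return LabeledImage(img, boxes_arr, np.zeros(len(boxes), dtype=int),
                        source_id=f"scene-{spec.rng_seed}")


def realized_overlap_fraction(item: LabeledImage) -> float:
    """Fraction of boxes intersecting at least one other box."""
    n = len(item.boxes)
    if n == 0:
        return 0.0
    hits = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if _boxes_intersect(item.boxes[i], item.boxes[j]):
                hits[i] = hits[j] = True
    return float(hits.mean())


def generate_dataset(n_images: int, out_dir, rng_seed: int = 0,
                     spec_ranges: dict | None = None) -> dict:
    """Write a dataset of rendered scenes with VOC XML and YOLO txt labels.

    ``spec_ranges`` may override per-image sampling ranges:
    ``n_spikes`` (lo, hi), ``overlap_target`` (lo, hi), ``canvas``,
    ``background`` (a choice list).  Returns (and writes) a manifest with
    per-image seeds, box counts, overlap fractions and image checksums.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    ranges = {"n_spikes": (25, 60), "overlap_target": (0.2, 0.45),
              "canvas": (640, 640), "background": ("green_similar",
                                                   "yellow_contrast")}
    ranges.update(spec_ranges or {})
    out_dir = Path(out_dir)
    for sub in ("images", "annotations", "labels"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(rng_seed)
    records = []
    for i in range(n_images):
        seed = int(master.integers(0, 2 ** 31 - 1))
        rng_i = np.random.default_rng(seed)
        spec = SceneSpec(
            canvas=tuple(ranges["canvas"]),
            n_spikes=int(rng_i.integers(ranges["n_spikes"][0],
                                        ranges["n_spikes"][1] + 1)),
            overlap_target=float(rng_i.uniform(*ranges["overlap_target"])),
            background=str(rng_i.choice(list(ranges["background"]))),
            rng_seed=seed,
        )
        item = generate_scene(spec)
        stem = f"scene_{i:04d}"
        item.source_id = stem
        from PIL import Image
        img_path = out_dir / "images" / f"{stem}.png"
        Image.fromarray(item.image).save(img_path)
        write_voc_xml(out_dir / "annotations" / f"{stem}.xml", item)
        write_yolo_txt(out_dir / "labels" / f"{stem}.txt", item)
        records.append({
            "stem": stem, "seed": seed, "n_boxes": len(item.boxes),
            "overlap_fraction": realized_overlap_fraction(item),
            "background": spec.background,
            "image_md5": file_md5(img_path),
        })
    manifest = {
        "rng_seed": rng_seed,
        "n_images": n_images,
        "images": records,
        "mean_boxes": float(np.mean([r["n_boxes"] for r in records])),
        "mean_overlap": float(np.mean([r["overlap_fraction"]
                                       for r in records])),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
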