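"""The improved YOLOv5s detector for wheat-spike detection.

Single-stage network: a Focus stem, a CSP backbone whose C3 blocks carry
efficient channel attention (ECA-C3), an SPP block, an FPN+PAN neck, and a
detection head in which each of the three scale branches passes through a
global attention mechanism (GAM) before its 1x1 prediction convolution.

Conventions that pin the per-layer parameter accounting:

* every composite Conv block is a bias-free 2-D convolution + affine batch
  norm + SiLU;
* C3 hidden expansion is 0.5; backbone repeats are (1, 2, 3, 1) with
  shortcuts, neck C3 blocks are single-repeat without shortcuts;
* ECA adds exactly k (=3) parameters to a C3 block;
* the Detect stage counts its three GAMs plus the three biased 1x1
  prediction convolutions.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .attention import EcaConfig, EcaGate, Gam
from .nn import (BatchNorm2d, Conv2d, Module, ModuleList, Tensor, concat,
                 max_pool2d_same, upsample2x)

__all__ = ["DEFAULT_ANCHORS", "ModelConfig", "LayerSpec", "Model",
           "build_model", "layer_param_counts", "decode_outputs",
           "decode_and_nms", "nms", "save_checkpoint", "load_checkpoint"]

# (w, h) anchor priors in input pixels, three per scale, ascending scale
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),       # stride 8
    ((30, 61), (62, 45), (59, 119)),      # stride 16
    ((116, 90), (156, 198), (373, 326)),  # stride 32
)

STRIDES = (8, 16, 32)


@dataclass
class LayerSpec:
    """One row of the layer table: where a layer reads from and what it is."""

    index: int
    from_: list[int]
    module_name: str
    args: tuple


# Layer table of the improved small model: (from, module, args).
# args: Conv/Focus -> (c_in, c_out, k, stride); C3/ECA-C3 -> (c_in, c_out,
# n_repeats, shortcut); SPP -> (c_in, c_out, pools); Concat/Upsample -> ().
_LAYER_TABLE = [
    ([-1], "Focus", (3, 32, 3, 1)),
    ([-1], "Conv", (32, 64, 3, 2)),
    ([-1], "ECA-C3", (64, 64, 1, True)),
    ([-1], "Conv", (64, 128, 3, 2)),
    ([-1], "ECA-C3", (128, 128, 2, True)),
    ([-1], "Conv", (128, 256, 3, 2)),
    ([-1], "ECA-C3", (256, 256, 3, True)),
    ([-1], "Conv", (256, 512, 3, 2)),
    ([-1], "SPP", (512, 512, (5, 9, 13))),
    ([-1], "ECA-C3", (512, 512, 1, True)),
    ([-1], "Conv", (512, 256, 1, 1)),
    ([-1], "Upsample", ()),
    ([-1, 6], "Concat", ()),
    ([-1], "C3", (512, 256, 1, False)),
    ([-1], "Conv", (256, 128, 1, 1)),
    ([-1], "Upsample", ()),
    ([-1, 4], "Concat", ()),
    ([-1], "C3", (256, 128, 1, False)),
    ([-1], "Conv", (128, 128, 3, 2)),
    ([-1, 14], "Concat", ()),
    ([-1], "C3", (256, 256, 1, False)),
    ([-1], "Conv", (256, 256, 3, 2)),
    ([-1, 10], "Concat", ()),
    ([-1], "C3", (512, 512, 1, False)),
    ([17, 20, 23], "Detect", ((128, 256, 512),)),
]


@dataclass
class ModelConfig:
    """Configuration of the detector (single class "spike" by default)."""

    nc: int = 1
    input_size: int = 640
    anchors: tuple = DEFAULT_ANCHORS
    strides: tuple = STRIDES
    eca: EcaConfig = field(default_factory=EcaConfig)
    use_eca: bool = True
    use_gam: bool = True
    gam_reduction: int = 4
    seed: int = 0

    def layer_specs(self) -> list[LayerSpec]:
        return [LayerSpec(i, list(frm), name, args)
                for i, (frm, name, args) in enumerate(_LAYER_TABLE)]

    def to_dict(self) -> dict:
        return {
            "nc": self.nc,
            "input_size": self.input_size,
            "anchors": [[list(a) for a in scale] for scale in self.anchors],
            "strides": list(self.strides),
            "eca": {"gamma": self.eca.gamma, "b": self.eca.b,
                    "kernel_mode": self.eca.kernel_mode},
            "use_eca": self.use_eca,
            "use_gam": self.use_gam,
            "gam_reduction": self.gam_reduction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        eca = EcaConfig(**d.get("eca", {}))
        anchors = tuple(tuple(tuple(a) for a in scale)
                        for scale in d.get("anchors", DEFAULT_ANCHORS))
        return cls(nc=d.get("nc", 1), input_size=d.get("input_size", 640),
                   anchors=anchors, strides=tuple(d.get("strides", STRIDES)),
                   eca=eca, use_eca=d.get("use_eca", True),
                   use_gam=d.get("use_gam", True),
                   gam_reduction=d.get("gam_reduction", 4),
                   seed=d.get("seed", 0))


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


class ConvBnAct(Module):
    """Bias-free convolution + batch norm + SiLU (the composite Conv block)."""

    def __init__(self, c1, c2, k=1, s=1, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, bias=False, rng=rng)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


class Focus(Module):
    """Space-to-depth stem: slice 3 channels into 12, then a 3x3 Conv block."""

    def __init__(self, c1, c2, k=3, s=1, rng=None):
        super().__init__()
        self.conv = ConvBnAct(4 * c1, c2, k, s, rng=rng)

    def forward(self, x):
        parts = [x[:, :, ::2, ::2], x[:, :, 1::2, ::2],
                 x[:, :, ::2, 1::2], x[:, :, 1::2, 1::2]]
        return self.conv(concat(parts, axis=1))


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, rng=None):
        super().__init__()
        self.cv1 = ConvBnAct(c1, c2, 1, 1, rng=rng)
        self.cv2 = ConvBnAct(c2, c2, 3, 1, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """Cross-stage-partial block with n stacked bottlenecks (expansion 0.5)."""

    def __init__(self, c1, c2, n=1, shortcut=True, rng=None):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = ConvBnAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBnAct(c1, c_, 1, 1, rng=rng)
        self.cv3 = ConvBnAct(2 * c_, c2, 1, 1, rng=rng)
        self.m = ModuleList([Bottleneck(c_, c_, shortcut, rng=rng)
                             for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        for block in self.m:
            y = block(y)
        return self.cv3(concat([y, self.cv2(x)], axis=1))


class EcaC3(C3):
    """C3 block with an ECA gate on the output of the final 1x1 fusion conv."""

    def __init__(self, c1, c2, n=1, shortcut=True,
                 eca_cfg: EcaConfig | None = None, rng=None):
        super().__init__(c1, c2, n, shortcut, rng=rng)
        self.eca = EcaGate(c2, eca_cfg)

    def forward(self, x):
        return self.eca(super().forward(x))


class SPP(Module):
    """Spatial pyramid pooling with stride-1 max pools of sizes 5/9/13."""

    def __init__(self, c1, c2, pools=(5, 9, 13), rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBnAct(c_ * (len(pools) + 1), c2, 1, 1, rng=rng)
        self.pools = tuple(pools)

    def forward(self, x):
        y = self.cv1(x)
        return self.cv2(concat([y] + [max_pool2d_same(y, k) for k in self.pools],
                               axis=1))


class Upsample(Module):
    def forward(self, x):
        return upsample2x(x)


class ConcatLayer(Module):
    def forward(self, xs):
        return concat(xs, axis=1)


class Detect(Module):
    """Three-scale head: per-scale GAM then a biased 1x1 prediction conv.

    Raw outputs are (B, 3, H_s, W_s, 5+nc) per scale: box offsets (4),
    objectness (1) and class logits (nc).
    """

    def __init__(self, channels=(128, 256, 512), nc=1, anchors=DEFAULT_ANCHORS,
                 strides=STRIDES, use_gam=True, gam_reduction=4, rng=None):
        super().__init__()
        self.nc = nc
        self.no = 5 + nc
        self.anchors = np.asarray(anchors, dtype=np.float32)
        self.strides = tuple(strides)
        from .nn import Identity
        self.gams = ModuleList([
            Gam(c, gam_reduction, rng=rng) if use_gam else Identity()
            for c in channels])
        self.preds = ModuleList([Conv2d(c, 3 * self.no, 1, bias=True, rng=rng)
                                 for c in channels])
        for conv in self.preds:
            # mild objectness prior so early training is not swamped by
            # background cells
            b = conv.bias.data.reshape(3, self.no)
            b[:, 4] = -4.0

    def forward(self, xs):
        outs = []
        for x, gam, pred in zip(xs, self.gams, self.preds):
            y = pred(gam(x))
            b, _, h, w = y.shape
            outs.append(y.reshape(b, 3, self.no, h, w).transpose(0, 1, 3, 4, 2))
        return outs


_STANDALONE = {"C3": C3, "ECA-C3": EcaC3, "SPP": SPP}


class Model(Module):
    """The assembled 25-layer detector."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        layers = []
        self.froms = []
        for spec in cfg.layer_specs():
            name, args = spec.module_name, spec.args
            if name == "Focus":
                m = Focus(args[0], args[1], args[2], args[3], rng=rng)
            elif name == "Conv":
                m = ConvBnAct(args[0], args[1], args[2], args[3], rng=rng)
            elif name == "ECA-C3":
                if cfg.use_eca:
                    m = EcaC3(args[0], args[1], args[2], args[3],
                              eca_cfg=cfg.eca, rng=rng)
                else:
                    m = C3(args[0], args[1], args[2], args[3], rng=rng)
            elif name == "C3":
                m = C3(args[0], args[1], args[2], args[3], rng=rng)
            elif name == "SPP":
                m = SPP(args[0], args[1], args[2], rng=rng)
            elif name == "Upsample":
                m = Upsample()
            elif name == "Concat":
                m = ConcatLayer()
            elif name == "Detect":
                m = Detect(args[0], nc=cfg.nc, anchors=cfg.anchors,
                           strides=cfg.strides, use_gam=cfg.use_gam,
                           gam_reduction=cfg.gam_reduction, rng=rng)
            else:  # pragma: no cover - table is fixed
                raise ValueError(f"unknown module {name}")
            layers.append(m)
            self.froms.append(spec.from_)
        self.layers = ModuleList(layers)

    @property
    def detect(self) -> Detect:
        return self.layers[-1]

    def forward(self, x) -> list[Tensor]:
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(
                f"input spatial dims must be divisible by 32, got {x.shape}")
        saved: dict[int, Tensor] = {}
        y = x
        needed = {idx for frm in self.froms for idx in frm if idx >= 0}
        for i, (m, frm) in enumerate(zip(self.layers, self.froms)):
            if isinstance(m, (ConcatLayer, Detect)):
                y = m([y if j == -1 else saved[j] for j in frm])
            else:
                y = m(y if frm[0] == -1 else saved[frm[0]])
            if i in needed:
                saved[i] = y
        return y  # Detect output: list of three tensors


def build_model(cfg: ModelConfig | None = None) -> Model:
    """Construct the improved detector from a config."""
    return Model(cfg)


def layer_param_counts(model: Model) -> list[tuple[int, int]]:
    """Trainable parameters per layer, in layer order."""
    return [(i, m.num_params()) for i, m in enumerate(model.layers)]


# ---------------------------------------------------------------------------
# Decoding and non-maximum suppression
# ---------------------------------------------------------------------------


def _np_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def decode_outputs(outputs, anchors=DEFAULT_ANCHORS, strides=STRIDES):
    """Map raw head outputs to absolute boxes and scores.

    Returns, per image, an (N, 4) xyxy array, an (N,) score array and an
    (N,) class array over all scales.  Offsets follow the bounded decode:
    ``xy = (2*sig(t_xy) - 0.5 + grid) * stride`` and
    ``wh = (2*sig(t_wh))**2 * anchor``.
    """
    anchors = np.asarray(anchors, dtype=np.float32)
    batch = outputs[0].shape[0] if hasattr(outputs[0], "shape") else len(outputs[0])
    per_image = [[] for _ in range(batch)]
    for s, out in enumerate(outputs):
        raw = out.data if isinstance(out, Tensor) else np.asarray(out)
        b, na, h, w, no = raw.shape
        stride = strides[s]
        sig = _np_sigmoid(raw)
        gy, gx = np.mgrid[0:h, 0:w].astype(np.float32)
        cx = (2 * sig[..., 0] - 0.5 + gx) * stride
        cy = (2 * sig[..., 1] - 0.5 + gy) * stride
        pw = (2 * sig[..., 2]) ** 2 * anchors[s, :, 0][None, :, None, None]
        ph = (2 * sig[..., 3]) ** 2 * anchors[s, :, 1][None, :, None, None]
        obj = sig[..., 4]
        cls = sig[..., 5:]
        conf = obj[..., None] * cls
        best_cls = conf.argmax(axis=-1)
        best_conf = conf.max(axis=-1)
        boxes = np.stack([cx - pw / 2, cy - ph / 2, cx + pw / 2, cy + ph / 2],
                         axis=-1)
        for i in range(b):
            per_image[i].append((boxes[i].reshape(-1, 4),
                                 best_conf[i].reshape(-1),
                                 best_cls[i].reshape(-1)))
    results = []
    for chunks in per_image:
        bx = np.concatenate([c[0] for c in chunks])
        sc = np.concatenate([c[1] for c in chunks])
        cl = np.concatenate([c[2] for c in chunks])
        results.append((bx, sc, cl))
    return results


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of xyxy box arrays (N,4) x (M,4)."""
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.clip(br - tl, 0, None).prod(axis=2)
    area_a = np.clip(a[:, 2:] - a[:, :2], 0, None).prod(axis=1)
    area_b = np.clip(b[:, 2:] - b[:, :2], 0, None).prod(axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    out = np.zeros_like(inter)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-sorted."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ious = _iou_matrix(boxes[i:i + 1], boxes[rest])[0]
        order = rest[ious < iou_thresh]
    return np.asarray(keep, dtype=int)


def decode_and_nms(outputs, conf_thresh: float = 0.25, iou_thresh: float = 0.45,
                   anchors=DEFAULT_ANCHORS, strides=STRIDES,
                   image_shape=None):
    """Decode head outputs and suppress duplicates per class.

    Returns, per image, a list of ``(box_xyxy, score, class_id)`` sorted by
    descending score; boxes are clipped to ``image_shape`` (h, w) if given.
    """
    if not 0 <= conf_thresh <= 1 or not 0 <= iou_thresh <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    results = []
    for boxes, scores, classes in decode_outputs(outputs, anchors, strides):
        mask = scores >= conf_thresh
        boxes, scores, classes = boxes[mask], scores[mask], classes[mask]
        if image_shape is not None:
            h, w = image_shape
            boxes[:, 0::2] = boxes[:, 0::2].clip(0, w)
            boxes[:, 1::2] = boxes[:, 1::2].clip(0, h)
        dets = []
        for c in np.unique(classes):
            sel = classes == c
            kept = nms(boxes[sel], scores[sel], iou_thresh)
            bsel, ssel = boxes[sel], scores[sel]
            dets.extend((bsel[i], float(ssel[i]), int(c)) for i in kept)
        dets.sort(key=lambda d: -d[1])
        results.append(dets)
    return results


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: Model, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights + config + version tag (.npz)."""
    meta = {"version": CHECKPOINT_VERSION, "config": model.cfg.to_dict(),
            "extra": extra or {}}
    state = model.state_dict()
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[Model, dict]:
    """Rebuild a model from a checkpoint; returns (model, extra-metadata)."""
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        state = {k: zf[k] for k in zf.files if k != "__meta__"}
    model = Model(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model, meta.get("extra", {})
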