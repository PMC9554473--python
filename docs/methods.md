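# Methods

## Problem setting

The package detects and counts wheat spikes (the grain-bearing
inflorescences) in 8-bit RGB field images taken above the canopy at heading
stage. Detection is single-class; the quantity of agronomic interest is the
per-image count, so the evaluation layer reports both detection quality
(recall, mAP) and counting agreement (RMSE, MAE, mean relative error).

## Network

The detector is a three-scale single-stage network of 25 layers:

| part | layers | content |
|---|---|---|
| stem | 0 | Focus: 2× space-to-depth (3→12 ch), 3×3 conv to 32 |
| backbone | 1–9 | stride-2 Conv + ECA-C3 stages, widths 64/128/256/512, C3 repeats (1, 2, 3, 1), SPP(5, 9, 13) before the last stage |
| neck | 10–23 | FPN (top-down, nearest-2× upsampling + concat) and PAN (bottom-up) with single-repeat, shortcut-free C3 blocks |
| head | 24 | per scale: GAM, then a biased 1×1 conv to 3·(5+nc) channels |

Conventions that the parameter accounting pins down (and the test suite
asserts layer by layer): composite Conv blocks are bias-free convolution +
affine batch norm + SiLU; C3 hidden expansion is 0.5 with bottleneck
expansion 1.0; backbone bottlenecks carry shortcuts, neck ones do not. With
these conventions the model has 15,628,418 trainable parameters.

### ECA

Channel attention at negligible cost: per-channel global average pooling,
one shared bias-free 1-D convolution across the channel axis, sigmoid,
multiply. The kernel-size rule k = |log2(C)/γ + b/γ|_odd (γ=2, b=1) is
implemented as `eca_kernel_size` with half-integer ties rounded to the
smaller odd number, but the detector defaults to a fixed k=3 for every
width: the per-stage cost of exactly +3 parameters is part of the
architecture's parameter ledger, whereas the adaptive rule would give k=5
for C ≥ 256. Adaptive mode is available via `EcaConfig(kernel_mode=
"adaptive")`. The ECA gate sits on the output of the block's final 1×1
fusion convolution; since the gate's cost does not depend on placement,
parameter accounting cannot distinguish alternatives, and this placement
gates the fused features that leave the block.

### GAM

Sequential channel and spatial attention designed to preserve cross-channel
× spatial interactions. Channel attention permutes C×H×W to H×W×C and
applies one two-layer MLP (C → C/r → C, r=4, rectifier nonlinearity,
biases on both layers) shared across spatial positions; spatial attention
applies 7×7 conv (C → C/r, bias) + batch norm + rectifier, then 7×7 conv
(C/r → C, bias) + batch norm, with no pooling anywhere. Both submodules
end in a sigmoid and multiply onto their input. Total cost 25C² + 5C
(reduction 4); bias and normalization placement is exactly the convention
that reproduces the detection head's 8,622,262-parameter count, which is
how these otherwise under-determined choices were fixed.

### Detection head and decoding

Raw head outputs are (B, 3, H_s, W_s, 5+nc). Boxes decode with the bounded
transform `xy = (2σ(t) − 0.5 + grid)·stride`, `wh = (2σ(t))²·anchor`, which
keeps sizes within (0, 4·anchor) and is the decode the loss inverts.
Objectness prediction biases initialize at −4 so that early training is not
dominated by the overwhelmingly negative background cells. Default anchors
are the conventional nine (10,13)…(373,326) pairs; they are refit to a
dataset only when the best-possible-recall gate fails (below).

## Loss

For each labeled box, every anchor within the size-ratio window
max(wh_t/wh_a, wh_a/wh_t) < 4 (per dimension) at every scale is matched at
the grid cell containing the box center. The composite loss is

* box: mean CIoU loss over matched pairs, weight 0.05;
* objectness: BCE over all cells, weight 1.0, positive targets set to the
  matched pair's CIoU similarity clamped to [0, 1] (detached);
* class: BCE over matched cells, weight 0.5.

α in the CIoU aspect term is a stop-gradient constant. c² is the squared
diagonal of the minimal enclosing axis-aligned box. The scalar
(`spikedet.boxes.ciou_loss`) and tensor (`spikedet.loss.ciou_tensor`)
implementations are independent code paths and are cross-checked against
each other in the tests.

## Preprocessing

* **Letterbox**: aspect-preserving resize with scale min(target/W,
  target/H), then the smallest padding that makes each dimension a multiple
  of the stride (32), split evenly, pad value 114. `square=True` pads to
  the full target for fixed-shape training batches. The inverse transform
  is exact.
* **Mosaic**: four sources, each rescaled by U(0.5, 1.5) on top of the
  fit-to-canvas scale, placed into quadrants around a center sampled
  uniformly from the middle half of a 2×-canvas working area; the output is
  the canvas crop around that center. Boxes are remapped, clipped, and
  dropped below 25% surviving area. Fully deterministic per seed.
* **Anchor gate**: before training, box sizes (at the training resolution)
  are checked against the current anchors with the per-dimension ratio-4
  rule; if the fraction of coverable boxes (best possible recall) is at
  least 0.98 the anchors are kept (and a log line says so), otherwise nine
  new anchors are fit by seeded k-means (k-means++ initialization, 10
  restarts) on standardized (w, h), and the fitted set is kept only if its
  BPR is at least the default's.
* **Tiling**: sliding 640-px windows with stride 320, last window snapped
  to the border; per-tile boxes are clipped and dropped below 30% surviving
  area. The overlap stride is a package choice; it guarantees every box
  smaller than the overlap survives intact in at least one tile.

## Training

SGD with momentum 0.937 and weight decay 0.0005 (decay applied to
convolution/linear weights only, not to norm parameters or biases), batch
size 8, initial learning rate 0.01, 60 epochs, 640-px inputs — these are
the package defaults. The schedule (a package choice) is a 3-epoch linear
warm-up followed by cosine decay to 0.01·lr0. Mosaic is applied with
probability 1.0 during training and never at evaluation. Training is
deterministic given the config seed on a fixed machine: the engine is pure
NumPy, and all sampling flows from one seeded generator.

## NumPy engine

`spikedet.nn` is a small reverse-mode autograd: conv2d as im2col + batched
GEMM (with a fast path for 1×1/stride-1 and backward-pass recomputation of
large column buffers to keep memory flat), a fused batch-norm op, SiLU /
sigmoid / ReLU, stride-1 max pooling, nearest 2× upsampling, indexing and
concatenation, and an SGD optimizer. All arithmetic is float32. Gradient
correctness is established by finite-difference tests per op.

## Synthetic scenes

The generator renders elliptical spikes (major axis 40–90 px, minor 12–22
px at the default 640 canvas, uniformly random orientation) with a
grain-row brightness texture and awn strokes, over a canopy background of
low-frequency illumination noise plus leaf-like streaks. Two color modes
emulate the hard and easy field cases: `green_similar` (spike ≈ background
hue) and `yellow_contrast`. Overlap is controlled by placing a target
fraction of spikes as intersecting pairs and rejection-sampling the rest;
the realized fraction of boxes intersecting another box tracks the target
within ±0.1 for scenes of ≥ 30 spikes. Boxes are computed from the
rendered pixel mask, so they are tight by construction, and scenes are
byte-identical per seed.

What the generator does **not** emulate: perspective and lens distortion,
spikes truncated at image borders, motion blur, specular lighting, growth-
stage variation, and the long-tailed density of real plots. Pipeline tests
on these scenes therefore establish that the machinery is correct and
trainable, not that field-accuracy numbers transfer.

## Numerical and scale choices

* Desk-scale smoke sizes: the pipeline overfit check uses eight 320-px
  scenes, batch 4, mosaic off, 30 epochs (about 3 minutes on one CPU);
  these sizes are the package's own test recipe.
* Sigmoid inputs are clipped at ±60 before exponentiation; gates can
  saturate to exactly 0/1 in float32 for |logits| beyond ~17.
* NMS is greedy per class with stable score ordering; ties in max-pool
  backward route gradient to the first maximal window position.
* Division guards (1e-9) appear in IoU/CIoU tensor code only where a
  degenerate zero-area enclosing box is arithmetically possible.
* AP uses the 101-point interpolated precision envelope; mAP@0.5:0.95
  averages thresholds 0.50:0.05:0.95.

## Known limitations

* CPU-only and desk-scale: full-resolution training at the default 640 px
  and 60 epochs is functional but slow (the engine targets transparency
  over throughput).
* Single-class by design; multi-class plumbing exists (nc > 1) but is not
  exercised by the shipped tests.
* The mean-error/mean-accuracy counting convention (mean relative count
  error, complement floored at 0) is one of several possible definitions;
  it is stated here because published tables rarely print the formula.
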