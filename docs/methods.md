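# Methods

`fegnet` counts objects in images of high-density fruit (the motivating case
is jujube orchards, where occlusion and scale variation make box-based
detection impractical) by regressing a *density map*: a non-negative grid
whose integral over any region is the expected object count there. This note
records the model, its assumptions, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Labels: point annotations → density maps

Each object is annotated with a single point at its center. A density label
is the sum of per-point kernels, each integrating to 1:

* **uniform** (default): unit mass spread evenly over an axis-aligned square
  window of side `window_side` (default 15 px, configurable) centered on the
  half-up-rounded point. Suited to near-spherical fruit whose surface
  appearance is roughly uniform — the label mimics the object's support
  rather than a peaked bump.
* **gaussian**: the classical crowd-counting alternative, a normalized
  discrete Gaussian (`sigma`, default 4 px) on the same window.

With `border_policy="renormalize"` a window clipped by the image border is
rescaled so the point still contributes exactly 1; the map total then equals
the point count to float precision (the property the whole method rests on,
and the invariant the test suite checks on random point sets). `"truncate"`
keeps the clipped kernel as-is and loses mass at borders; it exists for
ablation only.

Coordinates are 0-based, `x` = column, `y` = row, pixel centers at integers.
The foreground mask that supervises the enhancement module is the density
map binarized at threshold 0 (so the mask is exactly the union of kernel
supports) at full resolution, then max-pooled 8× onto the feature grid.
Binarizing before pooling preserves thin supports that averaging would dilute.

## Network

Three parts, all convolutional, built at a configurable `width_multiplier`
(every channel count scaled, minimum 1):

1. **Backbone** — the first ten 3×3 convolutions of VGG-16
   (64,64 / 128,128 / 256,256,256 / 512,512,512 with three 2×2 max-pools),
   ReLU after every convolution; output resolution is 1/8 of the input. At
   width 1 this block has exactly 7,635,264 parameters. Pretrained VGG
   weights can be loaded from a local `.npz` (width 1 only); otherwise
   He-normal initialization with a seed from the spec.
2. **Density regression head** — four 3×3 convolutions with dilation 2
   (channels 512, 512, 256, 128, scaled), ReLU between, then a 1×1
   convolution to one channel producing the raw density `O_d` at 1/8
   resolution. Dilation grows the receptive field to absorb object-scale
   variation without further pooling.
3. **Feature enhancement module (FEM)** — off a shared dilated 3×3
   convolution on the backbone features, two sibling paths, each a 3×3
   convolution + ReLU, a 1×1 projection and a sigmoid:
   * the *unsupervised* attention path emits `f ∈ (0,1)` which gates the raw
     density multiplicatively, `Den_f = O_d ⊙ f`, before 8× bilinear
     upsampling (align_corners=false) restores input resolution;
   * the *supervised* path emits a per-cell foreground probability trained
     against the pooled mask with binary cross-entropy. It shapes the shared
     features but does not touch the density directly.

Ablation variants: `baseline1` (no FEM — a CSRNet-style dilated regressor),
`baseline2` (attention path only), `baseline3` (supervised path only, no
gating), `full` (both).

Inputs are min–max normalized per image (or the usual ImageNet statistics
when pretrained weights are used) and zero-padded right/bottom to multiples
of 8; predictions are cropped back before counting. The predicted count is
the sum of the full-resolution density map.

### Initialization choices that matter on small budgets

Two departures from generic He initialization, both adopted after the
generic scheme failed to train at CPU scale:

* **Final 1×1 head layer is zero-initialized** (bias 0). Label densities
  are tiny (≈ 1/window-area per cell); a He-initialized head starts three
  orders of magnitude too hot and the optimizer spends its whole budget
  deflating it. Starting from the empty map and growing mass converges
  quickly. For the same reason the head output is *not* ReLU-clamped — a
  clamp makes the all-zero output a gradient-free absorbing state;
  non-negativity is enforced at density-map readout instead.
* **Attention gate starts open** (projection weights 0, bias +2, f ≈ 0.88).
  A randomly initialized multiplicative gate can collapse to f ≈ 0 early —
  suppressing all output is locally attractive before the head is useful —
  after which the head receives no gradient. Open-gate initialization is the
  same remedy used for forget gates in recurrent networks.

## Objectives

* **SSIM loss** (default): `1 − mean(L·C·S)` over 11×11 Gaussian windows
  (σ = 1.5), reflection-padded borders. Constants `c1 = (0.01R)²`,
  `c2 = (0.03R)²`, `c3 = c2/2` with data range `R = max(label)` per batch
  item (densities are small, so a fixed R = 1 would saturate the constants).
  The contrast term uses the `σx² + σy² + c2` denominator — the form under
  which identical maps score exactly 1; under `c3 = c2/2` the contrast and
  structure terms are computed in their collapsed product form, which avoids
  square roots of near-zero variances. Computed at full resolution against
  the full-resolution label.
* **Mask BCE**: pixel-mean binary cross-entropy of the supervised path's
  probabilities against the pooled mask, probabilities clamped to
  `[1e-7, 1 − 1e-7]`.
* **Total**: `w1 · density + w2 · mask`, weights (1, 1) by default; variants
  without a supervised path use the density term alone.
* Ablation alternatives: pixel-mean L1, MSE and smooth-L1 (transition at 1).

## Training

Adam at a constant learning rate (reference configuration: lr 1e-5,
600 epochs, batch 8 — for full-scale data on GPU-class hardware). Four
augmentations, applied per sample with labels regenerated from the
*transformed points* so mass conservation is exact under crops: random
square crop (`crop_fraction`, default 0.5, snapped to multiples of 8),
horizontal flip (p = 0.5; continuous x is mapped to `w−1−x` and clamped into
bounds), gamma in (0.5, 1.5) with p = 0.3, grayscale with p = 0.1. Training
crops to a fixed square per batch; validation/evaluation runs full images at
batch size 1. Model selection keeps the checkpoint with the lowest
validation MAE. All randomness derives from the config seed; two runs with
equal seeds produce identical histories.

## Metrics

MAE = mean |Z − Ẑ| over test images. The second customary metric is
reported twice: `mse_printed`, the literal mean of squared errors, and
`rmse = sqrt(mse_printed)`. Published counting tables are on the RMSE scale
(a table cannot have "MSE" 22.47 next to MAE 9.62 if it were a mean of
squares, which is bounded below by MAE²), so cross-method comparisons should
use `rmse`; both are emitted rather than guessing silently.

## Synthetic benchmark

`fegnet.synthetic` renders seeded orchard scenes: shaded reddish ellipses
(radius uniform in 3–8 px, hue-jittered) placed by rejection sampling with
pairwise occlusion capped at `max_overlap` (default 0.3), over a textured
green-brown background with non-fruit distractor ellipses; a global gamma
draw varies illumination. Scenes follow the four density classes used to
stratify real orchard data: low 1–50, medium 51–100, high 101–200, ultra
> 200 (capped at 300 to bound placement time). Ground truth is exact: every
rendered center is a point, including occluded ones.

The generator reproduces occlusion, scale change, clutter and illumination
variation in controlled form, but not the hard parts of real imagery —
leaf-colored fruit, specular foliage, motion blur, perspective-correlated
scale gradients, annotation noise. Passing the learning benchmark
demonstrates the pipeline's mechanics (labels, gradients, optimization,
evaluation) end to end; it does not certify accuracy on photographs.

### Desk-scale study configuration

The bundled study (acceptance suite and `scripts/acceptance.py`) trains the
width-0.125 `full` variant on 200 low/medium 128-px scenes and evaluates on
50 held-out scenes: 15 epochs, batch 4, 64-px random crops, Adam lr 1e-3,
**MSE density objective**. MSE rather than SSIM here is deliberate: from a
cold start on a few hundred steps, the SSIM objective has a strong local
optimum at the all-zero prediction (background windows already score 1), and
a tiny network falls into it for most seeds. MSE has no such optimum and its
gated-network configuration is itself one of the published ablations. At
this scale the trained network reaches a test MAE of roughly 4–13 fruit
against a zero-model MAE (mean true count) of ≈ 50 — a 75–91 % error
reduction across seeds. The reference-scale defaults (SSIM, lr 1e-5,
600 epochs) remain the package defaults for full-size training.

## Known limitations

* CPU-only NumPy execution: full-width training at published scale is out of
  reach; the engine is meant for correctness, small studies and inference.
* The uniform window side is global and fixed; adaptive per-object sizing is
  out of scope.
* `mse_printed`/`rmse` duality must be kept in mind when comparing numbers
  across papers.
* Pretrained backbone weights are supported only via a local `.npz` export;
  none are bundled.
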