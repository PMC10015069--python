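# Methods

## Problem and approach

`swarmcount` estimates the number of mosquitoes in a still image without
detecting or segmenting individual insects.  Each training image carries one
point annotation per mosquito.  The annotations are converted into a
*density map* — a non-negative field whose integral over any region is the
expected mosquito count there — and a convolutional network is trained to
regress that map from the raw image.  At inference the count is simply the
sum of the predicted map ("count by integration").  Density regression
tolerates touching and overlapping insects, which defeat detection- and
segmentation-based counters.

## Ground-truth density maps

An image with `N` annotated locations `x_i` is represented as a sum of
Dirac deltas, smoothed by an isotropic Gaussian:

```
F(x) = sum_i  delta(x - x_i) * G_sigma_i(x)
```

Mosquito apparent size varies between images (distance, optics), so each
image is assigned one of 8 empirical *size classes*, and the class fixes the
Gaussian width: `sigma = size_class + 1`, spanning sigma ∈ {2, …, 9} pixels.
The direction of the class→sigma mapping (whether class 1 is the smallest
or largest insects) is a convention; this package fixes sigma monotone
increasing in the class index and exposes `SIGMA_OF_CLASS` for replacement.

Numerical choices:

* **Truncation.** Kernels are cut at 4 sigma (side `2*ceil(4*sigma)+1`) and
  normalized to unit sum, so each point contributes total mass exactly 1 and
  the integral of the map equals `N` to float precision.
* **Boundary renormalization** (default on).  A kernel clipped by the image
  border is rescaled to unit mass over its visible part; with the flag off,
  points near the border lose mass and the integral under-counts.  Flagged
  because either convention is defensible; renormalization keeps the
  count-by-integration identity exact, which every closure test relies on.
* **Stamping, not FFT convolution.** With `N` points on an `H×W` grid,
  adding one truncated kernel per point costs `O(N * kernel²)` and is exact;
  a full-image convolution of the delta train gives the identical result at
  far higher cost for the sparse case.
* **Resolution.** The network predicts at 1/8 resolution (below), so maps
  are generated at full resolution and *sum-pooled* by 8 — each coarse cell
  is the sum of its 8×8 block, partial edge blocks summed as-is.  Sum
  pooling conserves mass exactly, unlike interpolation-based resizing.

## Network

Two stages, both fully convolutional, so any input size ≥ 4× the
downsampling factor is accepted.

**Front end (FEN).**  The convolutional prefix of VGG-16.  The default uses
the first 10 conv layers with only the first three max-pools (no pool after
the tenth conv), producing 512 channels at 1/8 resolution: deep enough for
mid-level texture features, while avoiding the information loss that extra
poolings inflict on few-pixel objects.  7-layer (2 pools, 1/4) and 13-layer
(5 pools, 1/32) variants exist for depth ablations.  Output spatial size is
the input size put through one floor-halving per pool.

**Regression head (AMRN).**  Three parallel branches with kernel sizes 3×3,
5×5 and 7×7 — receptive fields matched to small, medium and large apparent
insect sizes — each 3 convs deep with strictly decreasing channel widths
(default 256→128→64) and ReLU after every conv.  A squeeze-and-excitation
(SE) block gates the 7×7 branch: squeeze is a per-channel global average,
excitation a bottleneck `C → C/r → C` (default r = 16, hidden width floored
at 4) with ReLU then sigmoid, and the branch's feature map is rescaled
channel-wise by the resulting gates in (0, 1).  Branch outputs are
concatenated and fused to one channel by a 1×1 conv, followed by a final
ReLU (configurable) so predicted density — hence the count — is
non-negative.  All head convs use same-padding so the branches align for
concatenation.

The final ReLU is applied as an *output clamp*: predictions are always
non-negative, but the density loss is optimized on the unclamped map.
Training through the last ReLU is irrecoverably fragile — a single momentum
overshoot that pushes the whole map negative silences every gradient and
freezes the output at zero permanently (observed in pilots at several
seeds); optimizing the raw output keeps the gradient alive everywhere and
is the common practice in density-map regression.

Design points that were genuinely open and how they were fixed:

* *Branch widths*: only "successively decreasing" is prescribed;
  256→128→64 keeps the three branches symmetric and the fused width (192)
  moderate.
* *SE position*: after the branch's last conv, gating its final
  representation just before fusion.  The set of gated branches is a config
  field (`se_branches`), so no-attention / single-branch / all-branch
  variants are all constructible.
* *Initialization*: with no pretrained weights, convs use He (Kaiming)
  normal init — a Gaussian of std 0.01 throughout, common when the head
  sits on pretrained features, attenuates signal multiplicatively with
  depth and cannot train from scratch.  The 1×1 fusion conv instead gets
  narrow (std 0.01) weights and bias 0.01: a wide-init 1×1 over
  all-positive ReLU activations can start uniformly negative, in which case
  the final ReLU blocks every gradient and the output is frozen at zero.
* *Pretrained weights*: the package accepts a `.npz` of VGG-16 conv weights
  for the front end and applies ImageNet channel normalization when they
  are used; no weights ship with the package, and default runs use seeded
  random init with plain [0, 1] input scaling.

## Engine

No deep-learning framework is used: layers are implemented directly in
NumPy (float64).  Convolution is im2col — a sliding-window view reshaped so
the conv is one GEMM — with a col2im scatter-add backward; max-pooling is
2×2 stride 2 with floor semantics and argmax-routed gradients; every layer
implements an explicit `backward`.  The whole graph passes central-
finite-difference gradient checks at 1e-4 relative tolerance (see
`tests/test_nn.py`), and all computation is deterministic given the seeds,
which is what makes the bitwise-reproducibility contract of training
testable.

## Training

Loss is the Euclidean density loss

```
L(theta) = 1/(2N) * sum_i || P(X_i; theta) - P_i^GT ||²
```

over a batch of N images, on the network's output grid.  Optimization is
SGD with momentum (velocity form `v ← mu·v + g + wd·w`).  The reference
schedule is batch size 2, learning rate 1e-7, momentum 0.95, weight decay
5e-7 — rates sized for fine-tuning a pretrained front end; training the
reduced random-init model uses 2e-4 (below).

Batching of variable-size images uses fixed-size random crops (default
384×384, a multiple of 8 so prediction and pooled ground truth align);
ground truth for a crop is rebuilt from the points inside it, so crop mass
equals the contained count.  Evaluation always runs on full images.  Images
whose sides are not multiples of the output stride are edge-trimmed by at
most stride−1 pixels when trained uncropped.  Model selection keeps the
checkpoint with the best evaluation MAE, not the last epoch.  Runs are
bitwise reproducible from the seed (init, shuffling and crop positions all
derive from it).

## Metrics

Per-image predicted count `Y_i` = sum of the predicted map.  Aggregates:
`MAE = (1/N) Σ |Y_i − Y_i^GT|` (accuracy) and
`RMSE = sqrt((1/N) Σ |Y_i − Y_i^GT|²)` (robustness); MAE ≤ RMSE always.
Counts are reported as floats; the CLI offers `--round` for integer output.

## Synthetic data

Real swarm photographs of the kind this method targets (960×540 frames,
counts from 0 to a few hundred, 8 size classes, frequent adhesion) are not
redistributable, so the package ships a generator that reproduces their
*statistical* structure, not their appearance: a grey background with a
random-direction illumination ramp and Gaussian sensor noise; each mosquito
a dark anti-aliased ellipse (axis ratio 3:1, random orientation, intensity
30–90 against a 170 background) whose semi-major axis is 1.5× the size
class's sigma, keeping blob scale and kernel width consistent; with
probability `adhesion_prob` (default 0.2) a blob is placed within 1.5 blob
lengths of an existing one to create touching pairs.  Labels are exact by
construction: the annotation is the integer centre pixel of each ellipse.
Defaults: 540×960 frames, counts uniform in 0–150, uniform class mix.

What this does *not* emulate: wings/legs/body shape, motion blur, focus
variation, perspective-dependent size gradients within one image, and
non-uniform spatial clustering beyond pairwise adhesion.  Passing tests
therefore demonstrate that the pipeline is internally consistent and
trainable, not that field-image accuracy transfers.

## Verification experiments (`swarmcount.experiments`)

* **Count closure** — 100 seeded synthetic images, counts 0–200, all 8
  classes: pooled ground-truth mass must equal the annotation count
  (max |error| ≤ 1e-4), and evaluating the GT maps through the metric
  pipeline must give MAE, RMSE ≈ 0.
* **Overfit recovery** — 8 synthetic 128×128 images (counts 5–30, mixed
  classes), fit by a reduced model: 7-conv front end with widths
  (8, 8, 16, 16, 16, 16, 16), branch widths (12, 8, 6), SE on the 7×7
  branch, random init, learning rate 2e-4, up to 300 epochs.  The model
  must reach a training-set MAE below 20% of the mean true count; across
  training seeds 1, 2, 3, 5, 9 it reaches 1.1–2.4 (7–15%).  The reduced
  widths and small
  frames are the package's chosen desk-scale study size; the architecture
  is otherwise identical to the default.
* **Determinism** — two short runs with the same seed must produce
  bitwise-identical loss curves.

## Known limitations

* CPU-only float64 NumPy: full-width training at dataset scale (hundreds of
  960×540 images) is out of reach; the reference learning rate 1e-7 is kept
  as the default for fidelity, but practical runs here use the reduced
  model.
* No geometry-adaptive (k-NN) sigma; per-image class sigma only.
* No data augmentation beyond random cropping.
* Only VGG-16-style front ends; no alternative backbones or dilated
  back ends.
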