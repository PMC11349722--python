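# Methods

## The segmentation model

PlaqueNet is an encoder–decoder network for binary segmentation of
atherosclerotic plaque in 2D grayscale angiography slices. It has three
parts: a multi-path residual backbone (AResNet), a decode head built
from depthwise-atrous pyramid pooling and efficient channel attention
(DASPP-BICECA), and an auxiliary supervision branch (BINet) active only
during training.

### AResNet backbone

Each residual block holds C parallel branches (the *cardinality*). A
branch contributes two terms on the same block input x: the grouped
feature-extraction path G_i(x) (1×1 reduce → 3×3 grouped conv → 1×1
expand, with BN+ReLU inside) and a *deepwise residual optimization*
path

    H_i(x) = ReLU(BN(k_c * x + k_AP * x + b)),

i.e. a convolution path and an average-pooling path evaluated on the
same input and summed, then normalized and rectified. The block output
is the plain sum

    Y(x) = Σ_{i=1..C} (G_i(x) + H_i(x)) + x

with no activation after the sum, so a block whose branch parameters
are all zero is exactly the identity — an invariant the tests assert
bit-exactly. When a block changes channel count or stride, the skip is
a learned 1×1 projection. The pooling path preserves local averages
alongside the convolution features; together with the identity skip
this keeps input-level gradients alive at depth (asserted: mean
absolute input gradient > 1e-8 after one backward pass at standard
initialization).

Design choices where the architecture was genuinely open:

* **Branch evaluation.** The C branches are evaluated as grouped
  convolutions on a C-times-wider channel axis; this is algebraically
  identical to looping over branches and summing, which the tests
  verify against an explicit branch loop.
* **Final 1×1 of G_i carries no norm**, so Y(x) stays a plain sum over
  branch outputs (branch additivity is part of the test surface).
  ResNeXt-style blocks place a BN there; we trade that for the exact
  sum structure.
* **Where H_i attaches**: per branch, on the block input. Its pooling
  path is a 3×3, stride-1, same-padded average pool (window size
  configurable, odd so shapes are preserved); when the block changes
  shape, the pooled map passes through a 1×1 strided projection so the
  two paths can be summed.
* **Index ambiguity**: the defining sum for H_i uses one index for both
  the M stacked layers and the branch; we treat them as independent
  (M = `optimization_depth`, default 1).
* **Stage layout**: stem (two 3×3 stride-2 convs, total stride 4) plus
  configurable stages. The full-scale default mirrors a
  ResNeXt-50-style skeleton (blocks [3,4,6,3], C=32); the test suite
  and the scaled-down experiments use a miniature two-stage config
  (C=4, 8–16 channels) since the full model is far beyond what a
  single-CPU run can train.
* The decoder skip ("low level") taps the stem output at stride 4; the
  high-level map is the last stage output (stride 8 miniature / 16
  full).

### DASPP-BICECA decode head

DASPP runs one branch per atrous rate — each an atrous *depthwise* 3×3
convolution followed by a pointwise 1×1 (the depthwise-separable
factorization, kH·kW·C + C·O parameters instead of kH·kW·C·O) — plus an
optional global-average-pool branch, concatenates all branches and
fuses with a 1×1 projection. Default rates are (1, 6, 12, 18) plus the
pool branch, the Deeplab lineage default; the miniature config uses
(1, 2, 4) because its stride-8 grid is only 8×8.

BICECA computes a shared s = DSConv(Q) once, then

    q_avg = ReLU(GAP(s))            one descriptor per channel
    φ     = σ(LCCI(q_avg))          gates strictly in (0,1)
    η     = φ ⊗ s                   channel-broadcast multiply
    out   = ReLU(η ⊕ s)             residual add

LCCI is a length-k (default 3) 1D convolution across the channel axis
with circular extension and deliberately no bias, so a zero descriptor
maps to gates of exactly 0.5 — a frozen test point. The transform
between GAP and LCCI is the identity reshape by default (a learned
per-channel affine is available but off); the adaptive kernel rule
k ≈ odd(|log2 C / 2 + 1/2|) is provided but off by default. Because the
gates are a global statistic of the feature map, the head is
translation-covariant only in its convolution/resampling path; the
covariance test freezes the gates at 0.5 to isolate that path.

Bicubic resampling uses the Keys cubic-convolution kernel with
sharpness a = −0.5 (the near-universal "bicubic" default): 4 taps per
axis (16 neighbours), interpolating (δ(0)=1, δ(±1)=δ(±2)=0), partition
of unity to 1e-9, and exact reproduction of linear ramps in the
interior — all part of the test surface. Destination-to-source mapping
is the half-pixel-centre convention src = (dst+0.5)/scale − 0.5
(align-corners=false), stated explicitly because results differ between
conventions; out-of-range taps clamp to the edge sample.

Head flow: DASPP → BICECA → bicubic upsample to the stride-4 skip →
concat with 1×1-projected skip → 3×3 refine → 1×1 classifier → bicubic
upsample to input resolution. Two classes (background, plaque),
exposed as `n_classes`.

### BINet auxiliary branch and joint loss

BINet reads the same stride-4 backbone features as the decoder skip,
applies N (default 2) K×K (default 3) convolutions with *reflection*
padding — so constants pass without border attenuation, unlike zero
padding — then bilinear upsampling to input resolution and a 1×1
classifier. The bilinear step blends the 4 neighbours with corner
weights (1−αx)(1−αy), αx(1−αy), (1−αx)αy, αxαy and then applies F_Avg,
implemented as a stride-1 2×2 mean filter with edge-replicated padding
(shape- and constant-preserving); a config toggle disables it. The
stack is deliberately plain convolutions (no interleaved norm or
activation), matching its defining form; the branch input is already
rectified by the backbone.

The joint training objective is

    L_total = L_CE(main) + λ·L_CE(aux),      λ = 0.4 by default,

mean per-pixel softmax cross-entropy on both heads. λ is standard
auxiliary-head weighting; the combination form beyond "joint
cross-entropy" is not otherwise constrained, so the weight is
config-exposed. Optional inverse-frequency class weights exist but are
off by default. The branch writes nothing back into the main path, so
inference output is bit-identical with the branch enabled or disabled
— `inference_equivalence_guard` asserts this, and the guard is part of
the acceptance suite over 20 random models. The guarantee is about the
forward graph only: training *with* the auxiliary loss steers the
shared backbone differently (asserted via differing backbone
gradients), which is its purpose.

## Tensor engine

All operators run on a small float64 reverse-mode autograd engine over
numpy (`plaquenet.autograd`): strided/dilated/grouped 2D convolution
via patch-matrix multiplication, zero/reflect/edge padding with exact
scatter-add adjoints, matrix-based separable resampling (the bicubic
and bilinear operators are linear maps, so their adjoints are the
transposed weight matrices), a circular 1D convolution over channels,
and the usual elementwise/reduction primitives. Gradients are verified
against central finite differences throughout the test suite. All
convolutions are cross-correlations (no kernel flip), and the
brute-force oracles in the tests follow the same convention.

## Synthetic phantoms

No public dataset exists for this task, so `plaquenet.synthetic`
generates CCTA-like cross-sections: a bright contrast-filled lumen
inside a darker annular wall on a noisy background, with 1–3 eccentric
crescent-shaped plaque inclusions straddling the lumen/wall interface.
A crescent at angular centre θc with arc a and peak thickness t has
local thickness t·cos(π·d/a) for angular distance d, extending inward
from the lumen boundary and 0.6·t outward (capped at the outer wall).

Defaults (chosen once as a plausible scaled-down emulation): 64×64
canvas; vessel outer radius 13–22 px; wall 3–6 px; plaque arc 60–240°,
thickness 3–7 px, count 1–3; intensities background 0.15, wall 0.40,
plaque 0.65, lumen 0.80; Gaussian blur σ=0.6 then additive noise
σ=0.02. Rasterization is area coverage on a 4× supersampled grid
thresholded at 0.5; the mask is a pure function of the drawn geometry
(never of blur or noise). A deterministic redraw loop keeps the plaque
fraction within 0.1–20 % of pixels; across 200 default samples the
fraction spans more than a 5× range, so the task exercises multiple
scales. Each sample's random stream derives from (seed, index), so
datasets regenerate bit-identically and order-independently; the
default dataset size is 742 images split 519/223.

What the phantoms do *not* emulate: real CT noise texture and streak
artifacts, calcified vs lipid plaque intensity classes, neighbouring
anatomy, 3D partial-volume effects, or DICOM intensity scales. Passing
the scaled-down experiment therefore demonstrates that the
architecture, losses and pipeline function and learn as specified —
not clinical-grade performance on real CCTA.

## Training pipeline and problem sizes

Training is Adam (lr 1e-3, cosine decay by default — note the schedule
is a function of the run's total epoch budget) on min-max-normalized
images, batch 8, deterministic given the config seed (initialization,
shuffling and optional flip/rot90 augmentation all derive from it;
augmentation is off by default). NaN losses abort with the offending
batch ids and parameter norm. Checkpoints are flat named-tensor `.npz`
archives with the config and its hash alongside; optimizer moments and
the shuffle-RNG state are persisted each epoch so interrupted runs
resume deterministically. Evaluation reports micro (summed confusion
counts, the default) and macro (mean of per-image reports) versions of
IoU, Dice, accuracy, mIoU, mDice, MPA, precision, recall and F1, with
percentages rendered to two decimals.

Degenerate metric classes follow an explicit policy: absent from both
prediction and target → 1.0 (vacuous agreement); absent from target
but predicted → 0.0; both overridable. Per-class pixel accuracy is
TP/(TP+FN), and MPA is its unweighted class mean.

The scaled-down experiment used by the acceptance suite and
`scripts/acceptance.py` trains the miniature configuration on 160
phantoms for 30 epochs and evaluates 40 held-out phantoms (micro
aggregation); this fits in a few minutes on one CPU and reaches
held-out plaque Dice around 0.87–0.90. The suite also reports (without
gating) an early-epoch comparison of validation Dice with and without
the auxiliary loss over five seeds, since deep supervision is a
training aid whose benefit is seed-dependent at this scale.

## Numerical notes and limitations

* Float64 throughout; operator-vs-oracle agreement is asserted at
  1e-5, interpolation identities at 1e-9–1e-12, loss decomposition at
  machine precision.
* Sigmoid gates are mathematically inside (0,1) but saturate to 1.0 in
  float64 once the LCCI response exceeds ≈37; the strict-bounds test
  uses inputs below that regime.
* "Same" zero padding makes responses near borders deviate from the
  interior (constancy tests crop accordingly); the reflect-padded
  auxiliary stack does not attenuate constants at borders.
* Average pooling includes zero padding in its denominator at borders
  (it is implemented as a constant-weight depthwise convolution).
* The full-scale configuration (C=32, stage widths to 2048) is
  config-complete but not exercised by the tests; with H_i attached
  per branch its widest stage is very large, and training it is out of
  scope for this package's CPU-scale pipeline.
* Images whose sides are not divisible by the total stride are
  edge-padded and cropped back at prediction time; training data must
  be divisible (the generator's default canvas is).
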