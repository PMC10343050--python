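# Methods

## Problem and model

`hdcseg` segments gliomas in multimodal 3D MRI (T1, T1ce, T2, FLAIR,
stacked channel-first) into the BraTS label alphabet {0, 1, 2, 4}
(background, necrotic/non-enhancing core, peritumoral edema, enhancing
tumor), evaluated on the nested regions whole tumor WT = {1, 2, 4},
tumor core TC = {1, 4} and enhancing tumor ET = {4}.

The network is a lightweight U-shaped encoder–decoder:

* **Encoder.** A plain 3×3×3 convolution opens the network; each of the
  three subsequent coding units applies *periodic down-shuffling* (PDS),
  a 1×1×1 channel-reducing convolution, and a *hierarchical decoupled
  convolution* (HDC) block. PDS is a factor-2 space-to-depth
  rearrangement: spatial dimensions halve, channels octuple, and every
  output element equals exactly one input element, so downsampling is
  lossless and all learning stays in the convolutions. The output
  channel index encodes (source channel, x-parity, y-parity, z-parity)
  with the source channel varying fastest; this ordering is pinned in
  code so checkpoints are reproducible.
* **HDC block.** Dense 3D convolution is decoupled along space and
  channels: the input is split into g = 4 channel groups, each processed
  by an in-plane 3×3×1 convolution, with group *i* receiving group
  *i−1*'s output by element-wise addition before its convolution
  (hierarchical connection); the concatenated groups pass through a
  through-plane 1×1×3 sub-convolution that mixes all channels on the
  complementary view. Each convolution is followed by group
  normalization and leaky ReLU. For C→C channels this costs
  9C²/4 + 3C² parameters against 27C² for a dense 3×3×3 kernel.
* **Skip connections.** The two shallow skips are plain concatenation.
  The deepest skip hosts the *feature interaction module*: the skip
  feature X is (a) projected into an interaction space of K = 16 node
  features by learned softmax-over-space assignment maps (adaptive
  sampling) after a 1×1×1 channel reduction to 96 node channels,
  (b) mixed across nodes by the Laplacian-smoothing graph update
  X_G = σ((I − Â)·X_P·W) with a free K×K adjacency Â and 96×96 channel
  weights W (the 1×1-convolution realization), (c) re-projected to the
  voxel grid with the per-voxel node-renormalized assignments and
  embedded back to the skip width; in parallel a convolutional context
  branch produces X_C, refined by the global attention mechanism into
  X_A. A gated mean-field-style CGA-CRF recursion fuses the two streams:
  H_0 = X_A; H_t = G_t ⊗ M_t + (1 − G_t) ⊗ H_{t−1}, with
  G_t = σ(conv[H_{t−1}, X_G]) and M_t = conv(X_G), T = 2 iterations and
  convolutions shared across iterations. T = 0 returns X_A exactly,
  which pins the recursion's contract. The module's output concatenates
  X_F with the untouched X, so the decoder consumes both.
* **Global attention (GAM).** Sequential channel-then-spatial gating:
  F_2 = M_c(F_1) ⊗ F_1 and F_3 = M_s(F_2) ⊗ F_2. The channel map is a
  per-voxel two-layer MLP (C → C/4 → C, realized as 1×1×1 convolutions)
  under a sigmoid; the spatial map is two 7×7×7 convolutions
  (C → C/4 → C) under a sigmoid. Both gates lie in (0, 1), so the module
  never amplifies: |F_3| ≤ |F_1| elementwise. In the full model the GAM
  sits in the interaction module's context branch; in the GAM-only
  ablation arm it is applied to the deepest skip feature directly (the
  ablation grid needs a GAM site that exists without the interaction
  module, so a standalone placement had to be chosen).
* **Decoder.** Each stage reduces channels with a 1×1×1 convolution,
  upsamples ×2 trilinearly, concatenates the skip stream, and applies an
  HDC block; the head is a 1×1×1 convolution to 4 classes under a
  voxelwise softmax.

## Parameter budgets

Stage widths default to (16, 32, 64, 128). The design targets fixed
budgets — 1.20 M trainable parameters for the full model and 0.29 M for
the baseline (no interaction, no GAM) — while leaving the stage widths
free, so the widths were calibrated by exact enumeration of trainable
scalars to meet them. The intermediate interaction-only arm lands at
0.50 M with these internals (K = 16, 96 node channels, 1×1×1 CRF gate);
the ordering baseline < +interaction < full always holds structurally.
The test suite re-derives every count from closed-form per-layer
formulas.

## Training

Generalized Dice loss over the four classes,

GDL = 1 − 2·Σ_l ω_l Σ_n p_ln t_ln / Σ_l ω_l Σ_n (p_ln + t_ln),
ω_l = 1/(Σ_n g_ln)²,

with ω computed from the one-hot ground truth and clamped at 1e8 when a
class is absent from the patch so the loss stays finite. Optimization is
Adam (β = 0.9/0.999) with polynomial learning-rate decay
lr·(1 − step/total)^0.9 and L2 weight decay 1e-5; the defaults are
lr 1e-4 and decay 1e-5, both overridable (common alternatives in this
architecture family are lr 1e-3 and decay 5e-4). Augmentation: independent mirror flips per plane
(p = 0.5), in-plane rotation uniform in [−10°, 10°] (trilinear for
intensities, nearest-neighbour for labels), per-modality intensity
jitter x → x·s + b with s ∈ [0.9, 1.1], b ∈ [−0.1, 0.1]. Patches default
to 128³ at BraTS scale; intensities are z-scored per modality over
nonzero voxels (background stays exactly 0). For inference the depth
axis is zero-padded to the next multiple of 8 (155 → 160 in BraTS
geometry) and cropped back after the argmax.

## Synthetic phantoms

The phantom generator emulates the *structure* of a BraTS case so every
pipeline stage runs with no download: a brain ellipsoid on a zero
background with three nested ellipsoidal tumor compartments (edema
shell = label 2, necrotic shell = label 1, enhancing core = label 4),
per-modality compartment mean intensities from a contrast table chosen
to mimic clinical appearance (edema bright on FLAIR/T2, enhancing core
bright on T1ce), and i.i.d. Gaussian noise with σ = 0.1 against
compartment contrasts of 0.3–0.8 — a moderate-noise, fully separable
regime. Default size 64³ keeps CPU tests in seconds; tumor radii are
drawn from 0.18–0.30 of the volume edge with ±20 % per-axis
ellipticity. The phantoms do **not** model MRI physics: no bias fields,
partial-volume effects, anisotropic spacing, multi-focal disease, or
inter-rater label noise. Tests passing on phantoms therefore demonstrate
that the implementation is correct and that the network has the capacity
to learn nested-compartment contrast patterns — not that it reaches any
particular accuracy on clinical data.

## Numerical and design choices

* **Autodiff engine.** The network runs on a compact in-repo
  reverse-mode automatic-differentiation engine over NumPy arrays
  (`hdcseg.autograd`), covering exactly the operations the model needs;
  convolution uses an im2col/tensordot forward with an explicit
  scatter-add adjoint. Every operation is validated against central
  finite differences in float64.
* **Normalization.** Group normalization (up to 8 groups) everywhere: it
  is stateless and batch-independent, so single-device evaluation is
  bit-deterministic. (The description's "synchronized normalization"
  presumes multi-GPU batch statistics.)
* **Activation.** "ReLU with a slope of 0.01" is read as leaky ReLU with
  negative slope 0.01.
* **PDS index arithmetic.** The printed index formulas contain floor
  terms that evaluate to zero for all valid indices and therefore cannot
  define a bijection; the implementation uses the canonical factor-2
  space-to-depth rearrangement, which satisfies every stated property
  (C′ = 8C, spatial halved, pure rearrangement, exactly invertible).
* **Label mapping.** Label conventions in circulation disagree on which
  raw label is enhancing tumor; the standard BraTS convention (4 = ET,
  2 = edema, 1 = NCR/NET) is the default since the official validation
  servers use it. The mapping is a parameter of `labels_to_regions`.
* **Hausdorff reading.** The printed formula is the 100th-percentile
  (classical) Hausdorff distance although the metric is named HD95; both
  are implemented, defaulting to the 95th percentile of the pooled
  directed boundary distances (the BraTS-standard reading). Boundaries
  are voxels with a 6-neighbour outside the mask; distances are
  Euclidean in voxel units, optionally scaled by the voxel spacing.
  Empty-mask policy: Dice(∅, ∅) = 1, Dice(∅, ·) = 0; HD(∅, ∅) = 0
  flagged, HD with one empty mask reports the volume diagonal, flagged.
* **Adjacency.** Whether Â is input-conditioned or free is ambiguous;
  it is a free parameter here (the 1×1-convolution reading), initialized
  at zero so the first graph update is a pure per-node channel mix.

## Overfit sanity run

The end-to-end training check memorizes four 64³ phantoms with a
width-reduced full network (widths 8, 16, 32, 48) and requires final
training GDL < 0.1 together with whole-tumor Dice > 0.9, within 200
optimization steps. The run uses Adam at lr 2e-2 (polynomial decay),
which at this reduced width converges an order of magnitude faster than
the BraTS-scale default; problem sizes (4 cases, 64³, 200 steps) were
chosen so the whole check completes in about ten minutes on one CPU
core. The binding constraint is the whole-tumor boundary: the
generalized Dice weights make over-segmenting the edema rim by one voxel
nearly free, and group-norm statistics differ between small
tumor-centered patches and whole volumes, so the run trains on whole 64³
volumes — matching the evaluation scale and giving the background its
full evidence. Under these settings the run reaches GDL ≈ 0.004 and
whole-tumor Dice ≈ 0.98 on the four phantoms.

## Known limitations

* CPU-only NumPy execution: throughput suits tests and phantom-scale
  studies, not BraTS-scale training (which the design targets on GPUs).
* FLOP accounting is out of scope (multiply-accumulate conventions
  vary and no single convention is pinned here).
* The CGA-CRF recursion is a pinned gated mean-field contract, not a
  derivation from a specific CRF energy; its testable anchors are the
  T = 0 identity and the closed-gate limit.
* Single interaction module at the deepest skip; the shallower skips are
  plain concatenation (configurable placement is not exposed).
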