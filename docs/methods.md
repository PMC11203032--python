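# Methods

## Problem and data model

Brain-tumor segmentation on multi-modal MRI assigns every voxel one of
the labels {0 background, 1 necrotic/non-enhancing core, 2 peritumoral
edema, 4 enhancing tumor}. Evaluation happens on three nested binary
regions derived from the labels: whole tumor WT = {1, 2, 4}, tumor core
TC = {1, 4}, enhancing tumor ET = {4}. A case directory holds four
co-registered, skull-stripped modalities (T1, T2, T1ce, FLAIR) as NIfTI
volumes; voxels outside the brain are exactly zero, which the
preprocessing exploits.

## Preprocessing and augmentation

Per channel: intensities are clipped to the 1st/99th percentile of the
nonzero-voxel distribution (linear-interpolation percentiles — stated
because percentile dialects differ), then standardized to zero mean and
unit population variance over the nonzero voxels; background zeros stay
zero. A fixed-size patch is then cropped, drawn uniformly among windows
containing the brain bounding box (zero-padding first when the volume is
smaller than the patch; when the box exceeds the patch, among
maximum-overlap windows). Augmentation applies, independently with
probability `p_apply` (default 0.5) per transform: rotation by
U(−30°, 30°) in a random orthogonal plane (linear interpolation for
intensities, nearest-neighbour for labels), additive Gaussian noise of
sd 0.1, Gaussian blur with sigma U(0.5, 1), and a gamma transform with
exponent U(0.7, 1.5) applied to per-channel [0, 1]-rescaled intensities
(so standardized, signed data is handled). The label volume is only ever
transformed geometrically. The pipeline order is read → clip+Z-score →
crop → augment.

Note that the percentile clip is *not* idempotent on noisy data: a
second application re-clips the 1% tails of the already-clipped
distribution and shifts the statistics at the 1e-3 level. On
piecewise-constant (noise-free) data it is exactly idempotent.

## Architecture

Input `(4, D, H, W)` → patch partition (default 4³) and linear embedding
to width C₀ → encoder stages → two-layer ECSA bottleneck → mirrored
decoder stages → final ×patch expansion → 1×1×1 classifier emitting
three region logit channels trained against the (overlapping) WT/TC/ET
binary targets; at inference, sigmoid → 0.5 threshold → hierarchy
enforcement (TC := TC∧WT, ET := ET∧TC) → label encoding.

**Encoder stage i** (width C₀·2ⁱ): `depths[i]` transformer block pairs —
pre-norm W-MSA then pre-norm SW-MSA, each followed by a LayerNorm+MLP
residual — then one GNS block, then patch merging. Window attention uses
scaled dot product with a learned 3D relative position bias (switchable)
and a shift of half the window per axis; cross-boundary token pairs
under the cyclic shift are masked with a −1e9 additive bias, which
underflows to exactly zero attention weight.

**Patch merging** concatenates a 2×2×2 neighbourhood (depth-halving,
default) or a 1×2×2 neighbourhood (fixed-depth variant) and reduces
linearly to 2C. The analytic MAC counter (`count_macs`; one MAC = one
scalar multiply-add, normalizations/activations uncounted) shows the
depth-halving layout strictly cheaper for any multi-stage configuration,
since deeper stages see 8× rather than 4× fewer tokens per merge — a
20.7% total reduction for the toy profile at 32³.

**GNS block**: channel split into halves; the left half passes through
untouched; the right half runs 1×1×1 conv → Unit 1 → depth-wise 3×3×3
conv (zero padding 1) → Unit 2 → 1×1×1 conv → Unit 3; concat; channel
shuffle with 2 groups (the two branches). The default unit layout is
GN+GeLU / GN / GN+GeLU; the original BN+ReLU / BN / BN+ReLU layout and
the other placements remain selectable (`gns_layout` ∈ A…E). With batch
size 1, "BN" is per-channel normalization over the sample's voxels. GN
group count defaults to the largest divisor of the branch width not
exceeding 8 (a fixed cap would not divide tiny test widths). The GNS
output replaces the stage features (no extra residual), matching the
sequential pipeline drawing.

**ECSA bottleneck**: two Enhanced Transformer layers
`y = ECSA(LN(x)) + x; z = y + MLP(LN(y))`, the conventional pre-norm
residual pair. Inside ECSA, gates are
`sigmoid(FL(ReLU(FL(AP(x)))))` with square linear maps (no reduction
ratio); the Q/K gates read linearly projected features, the V gate the
raw features, all with independent parameters (whether the linear maps
are shared is unstated; independence is the safer reading). The fusion
is `FL(softmax(Conv₁ₓ₁ₓ₁(DWC₇ₓ₇ₓ₇(K′⊙Q′))) ⊙ V′)` with the softmax over
the **channel** axis (the block is channel attention; the axis is
configurable). The 7×7×7 depth-wise kernel uses zero padding 3 so the
residual shapes match. The bottleneck order is ECSA ×2 then patch
expanding.

**Decoder stage**: each block pair mirrors the encoder pair; every
sub-layer projects queries from the decoder features and runs, in
parallel, self-attention (own K/V) and cross-attention against the K/V
cached by the matching encoder sub-layer (the shifted sub-layer uses the
shifted cache and mask). The branches merge as
`(1−λ)·CA + λ·SA`, λ = 0.5 by default — the balanced setting found best
by ablation — then Fourier positional encoding is added per in-window
token position, and a LayerNorm+MLP residual follows; the sub-layer adds
the merged result to its input stream. The sinusoidal code uses
`sin/cos(p / f^(2i/dim))` with frequency coefficient f = 10 000
(wavelengths in geometric progression). Encoder caches are consumed in
mirror order: encoder block j of stage i feeds decoder block
(depths[i]−1−j) of the same stage, so the deepest encoder block pairs
with the first decoder block.

## Training

Plain soft Dice loss, `1 − mean_r (2Σpt + ε)/(Σp + Σt + ε)` with
ε = 1e-5, optimized with Adam (β = 0.9/0.999, eps 1e-8), batch size 1.
The full-scale `RunConfig` defaults mirror the published recipe:
learning rate 1e-4, 350 epochs, 128³ crops. The desk-scale toy profile
(`toy_run_config`: 32³ crops, C₀ = 8, depths (2, 2), window 2³, no
augmentation) uses learning rate 3e-3: Adam's per-parameter step is
bounded by roughly the learning rate, so 1e-4 is sized for a
350-epoch × thousand-case budget, while the toy profile is meant to
overfit a single phantom in a few hundred steps — at 3e-3 it reaches
soft-Dice loss near or below 0.1 within 250–400 steps (seed-dependent;
the reproduction script runs 400), whereas at 1e-4 the same model
descends monotonically but is still near loss 0.58 after 1 800 steps.

## Metrics

Dice = 2TP/(2TP+FP+FN); sensitivity = TP/(TP+FN); specificity =
TN/(TN+FP); HD95 = max of the two directed 95th percentiles (linear
interpolation) of boundary-to-boundary nearest distances, scaled by the
voxel spacing (default 1 mm isotropic, where voxel and mm units
coincide). Boundary voxels are mask voxels with ≥1 background
face-neighbour (6-connectivity; the volume border counts as background).
Empty-mask conventions, fixed here because leaderboards differ: both
masks empty → Dice 1; a zero denominator in sensitivity/specificity →
`nan` (reported missing); HD95 with an empty boundary set → `nan`
sentinel, never a silent 0. Dice and HD95 as defined are symmetric in
prediction and truth.

## Synthetic phantoms

A phantom is a brain ellipsoid (semi-axes 0.45 of each grid dimension)
of nonzero intensity on an exactly-zero background, with three nested
axis-aligned lesion ellipsoids (default semi-axes 10/6/3 voxels on a 32³
grid, i.e. a whole tumor spanning ~60% of the grid diameter — lesion
proportions in the range real cohorts show) encoded with the standard
label alphabet. Intensities are piecewise-constant tissue means per
modality — edema brightest on the FLAIR-like channel, the enhancing rim
brightest on the T1ce-like channel, matching the qualitative contrast of
real sequences — plus Gaussian noise of sd 0.05, clipped away from zero
inside the brain. Geometry, contrast and seed live in `PhantomSpec`;
identical specs are bit-identical.

What the phantoms do *not* model: MRI physics (bias fields, partial
volume, anisotropic spacing), anatomy, multifocal or irregular lesions,
inter-rater label noise. Tests passing on phantoms therefore certify the
implementation — shapes, equations, determinism, trainability — not
clinical segmentation quality; the published-scale numbers require the
real cohort, GPU-scale training and the hidden validation server.

## Numerical choices

* float64 throughout the autodiff core; clarity over memory at desk
  scale.
* Attention mask value −1e9 (softmax weight underflows to exact 0);
  softmax stabilized by subtracting the row max as a constant.
* LayerNorm/GroupNorm ε = 1e-5; soft-Dice ε = 1e-5.
* Weight init: uniform ±1/√fan-in for linear/conv maps, N(0, 0.02) for
  the relative-bias tables; a seeded generator makes models
  reproducible.
* Degenerate inputs: all-zero channels are rejected before Z-scoring; an
  ET radius of 0 yields a legal phantom with an empty enhancing region;
  empty-region metric conventions as above.
* Checkpoints embed the model config as JSON inside the `.npz` archive.

## Known limitations

* Single-sample processing (batch size 1) only — consistent with the
  recipe, and group/layer norms make it statistically sound, but there
  is no batching speed-up.
* The analytic MAC count covers linear, attention and convolution terms
  with one fixed convention; absolute totals are not comparable across
  counting conventions, only orderings are asserted.
* CPU-bound: the toy profile trains in minutes, but the full 128³
  configuration is impractical without an accelerator backend.
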