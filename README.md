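# getnet

A volumetric transformer U-Net for brain tumor segmentation on
multi-modal MRI, combining 3D shifted-window self-attention with two
convolutional blocks that restore local detail: a
**group-normalization-shuffle (GNS)** unit after every encoder stage and
an **enhanced channel self-attention (ECSA)** bottleneck. The package is
aimed at researchers who want a tested, CPU-runnable reference
implementation of this architecture family — every block is checked
against independent brute-force oracles, and a synthetic phantom
generator stands in for the BraTS data so nothing needs downloading.

## The model

A case is four co-registered modalities (T1, T2, T1ce, FLAIR) over a
skull-stripped brain; evaluation uses three nested binary regions
decoded from the labels — whole tumor WT ⊇ tumor core TC ⊇ enhancing
tumor ET.

The network is U-shaped:

* **Encoder** — non-overlapping patch embedding, then per stage: a
  transformer block pair (window attention W-MSA followed by
  shifted-window attention SW-MSA), a GNS block, and patch merging that
  halves **all three** spatial axes while doubling channels (the
  fixed-depth variant that keeps the depth axis is available for
  comparison and costs strictly more multiply–accumulates).
* **GNS** (split → 1×1×1 conv → depth-wise 3×3×3 conv → 1×1×1 conv →
  concat → channel shuffle) with group normalization and GeLU in the
  layout GN+GeLU / GN / GN+GeLU.
* **Bottleneck** — two Enhanced Transformer layers
  `y = ECSA(LN(x)) + x; z = y + MLP(LN(y))`, where ECSA gates channels
  with squeeze-style weights Q_w, K_w, V_w and fuses
  `FL(softmax(Conv₁ₓ₁ₓ₁(DWC₇ₓ₇ₓ₇(K′⊙Q′))) ⊙ V′)`.
* **Decoder** — per stage, parallel self-attention and cross-attention
  (keys/values bridged from the matching encoder layer), merged by the
  convex combination `(1−λ)·CA + λ·SA` (λ = 0.5) plus Fourier positional
  encoding (frequency 10 000), LayerNorm and an MLP; patch expanding
  restores resolution, and a 1×1×1 classifier emits one logit per
  region.

Training uses plain soft Dice loss over the three region channels with
Adam. Evaluation reports per-region Dice, 95th-percentile Hausdorff
distance (mm), sensitivity and specificity.

Everything runs on a small reverse-mode autodiff core over numpy
(`getnet._tensor`) — no GPU or deep-learning framework is required.

## Worked example

```bash
getnet synth -n 2 --seed 7 -o cases
getnet train -d cases -o model.npz --steps 250 --seed 0
getnet predict -c model.npz --case-dir cases/GETNET_SYN_000 -o preds
getnet predict -c model.npz --case-dir cases/GETNET_SYN_001 -o preds
getnet evaluate --pred-dir preds --truth-dir cases -o metrics.csv
```

prints (abridged):

```
wrote 2 cases to cases
trained 250 steps on 2 cases; final loss 0.1793; checkpoint model.npz
                 dice_WT   hd95_WT ...  dice_TC ...  dice_ET
GETNET_SYN_000  0.867849  1.732051 ... 0.893949 ... 0.756972
GETNET_SYN_001  0.873215  2.000000 ... 0.873091 ... 0.820896
mean            0.870532  1.866025 ... 0.883520 ... 0.788934
```

`synth` writes BraTS-layout phantom cases (four modality NIfTI volumes
plus labels, nested ellipsoid lesions on a zero background). `train`
runs the preprocessing chain (clip to the 1st/99th nonzero percentiles,
Z-score over nonzero voxels, random brain-containing crop) and optimizes
the desk-scale toy profile (32³ input, embedding width 8). The final
soft-Dice loss of 0.18 after 250 steps on two cases, and mean region
Dice of 0.87/0.88/0.79 (WT/TC/ET) with HD95 around 1–2 voxels, show the
toy network fitting the phantoms; at this tiny scale the numbers
measure the plumbing, not clinical performance.

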