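# Methods

## Problem and models

`neurograde` classifies single-channel 3D brain MR volumes into three
classes — low-grade glioma (LGG), high-grade glioma (HGG) and healthy —
using "spatiospatial" residual networks: video (spatiotemporal)
architectures applied to volumes by treating the slice axis as the
pseudo-temporal axis.  Three 18-layer variants share one skeleton (stem →
four stages of two basic residual blocks at widths 64/128/256/512 → global
adaptive average pooling → dropout 0.3 → linear head):

| variant | stem | stage conv modes |
|---|---|---|
| `resnet3d` | 3D conv (3,7,7), stride (1,2,2) | 3D, 3D, 3D, 3D |
| `resnet2p1d` | 2D 7×7 → 45 ch, then 1D k3 → 64 ch | (2+1)D in all stages |
| `resnet_mixed` | 3D conv (3,7,7), stride (1,2,2) | 3D, 2D, 2D, 2D |

A (2+1)D convolution factorizes a t×d×d kernel into an in-plane d×d
convolution and a slice-axis t convolution with batch-norm and ReLU in
between; its internal width is `floor(t·d²·n_in·n_out / (d²·n_in +
t·n_out))`, computed once per block from the block's input/output widths,
so its parameter budget approximates the unfactorized convolution.
Residual blocks are post-activation (conv→BN→ReLU→conv→BN, add identity,
ReLU); stages 2–4 downsample with a stride-2 first conv (in-plane only for
the 2D stages of the mixed model) and a kernel-1 strided conv + BN on the
identity path.  All convolutions are bias-free, batch-norms are affine and
the head carries a bias; under these conventions the full-width mixed and
(2+1)D models count 11,472,963 and 31,297,254 trainable parameters exactly.
The full-width pure-3D model counts 33,148,995; `architecture_summary()`
emits the complete layer table so any count can be audited layer by layer.

All layers (convolution, batch-norm, ReLU, dropout, adaptive pooling,
linear) and the Adam optimizer are implemented directly on NumPy with
hand-written reverse-mode gradients, validated against finite differences
in the test suite.  Convolutions are evaluated as one GEMM over an im2col
buffer built per kernel offset; the stem skips its input gradient (nothing
is below it).

## Objective

Class imbalance is handled by normalized per-class weights
`W_c = 1 − samples_c / samples_t` (so Σ W_c = n−1; for the 73/259/259
cohort, W ≈ (0.876, 0.562, 0.562)).  For a sample of true class c the loss
is `−W_c · log softmax(logits)[c]`; the total is the sum of per-class terms
and the batch reduction is the mean (inert at batch size 1, but defined).

## Batch-norm semantics at batch size 1

Training uses single-sample steps, so batch-norm statistics are per-sample
(per channel over the spatial axes).  Evaluating with exponentially
averaged running statistics — the large-batch convention — produced
severely degraded, single-class predictions in desk-scale experiments:
with so few optimization steps the network's learned function depends on
per-sample normalization, which fixed population statistics do not
reproduce.  `NetworkConfig.bn_track_running_stats` therefore defaults to
`False`: per-sample statistics are used in evaluation as well (the standard
`track_running_stats=False` configuration for batch-size-1 pipelines).
Evaluation remains fully deterministic.  Classic tracking is available
behind the flag, together with `calibrate_batchnorm()`, which re-estimates
running statistics with one sweep over unaugmented training samples.

## Preprocessing and augmentation

* Intensity normalization: clip to the volume-wide [0.5, 99.5] percentiles,
  then map affinely to [0, 1].  The map is monotone and invariant to
  positive affine intensity transforms.  Percentiles are per-volume, over
  all voxels (no foreground masking).  A z-score variant after clipping is
  a plausible alternative reading of the usual recipe; clip-and-rescale is
  the simpler reading and the one implemented.
* Resampling: trilinear onto a 2 mm isotropic grid; the output extent per
  axis is `round_half_up(dim · spacing / target)` (the rounding rule must
  be pinned for reproducibility; e.g. a 240×240×155 grid at 1 mm maps to
  120×120×78).  Resampling at the native spacing is the identity.
* Light augmentation (training only, applied on the fly per sample per
  epoch): random isotropic scale in [0.9, 1.2] and random rotations up to
  10° per axis about the volume centre (trilinear, zero fill), then a
  left-right flip with probability 0.25.  Evaluation never augments.
  Heavier schemes (elastic, k-space artefacts) are deliberately excluded.

## Evaluation protocol

Three *independent* stratified random splits at a 7:3 train:test ratio
(per class, test count = `round_half_up(0.3 · n_c)`; for class sizes
73/259/259 this is 22/78/78).  Per fold: fresh network, fresh class
weights from the fold's training counts only, Adam (lr 1e−5, weight decay
1e−3 at full scale), batch size 1, no early stopping or schedule.  The
reported model is by default the final-epoch weights;
`TrainConfig.average_last_epochs > 1` instead averages the weight
snapshots taken at the end of each of the last k epochs (tail/Polyak
averaging).  With single-sample steps the end-of-epoch weights are a noisy
draw around the converged solution — in desk-scale runs neighbouring
epochs' endpoints produced test accuracies differing by 0.2 and more —
and the tail average is a far more stable estimate that uses no held-out
information.  Desk-scale runs use k = 5.  Reports: per-fold confusion matrices; per-class precision,
recall, specificity, F1; per-class mean ± sample-SD F1 over folds; macro
and support-weighted F1 and accuracy on the pooled (summed) confusion
matrix, with the mean of fold accuracies reported alongside.  Zero
denominators in any metric yield 0 with a warning.

## Phantom generator

Phantoms emulate skull-stripped contrast-enhanced T1 appearance at the
minimum level of detail that makes the three classes separable by
construction: an ellipsoidal brain (85% of each axis) of mean intensity
0.5 (voxel texture SD 0.02) on an exactly-zero background; spatially
correlated scanner noise (white Gaussian of SD 0.05 smoothed with a
1-voxel kernel — magnitude MR noise on an interpolated grid is correlated,
and smoothing keeps single-voxel extremes bounded); one lesion per
pathological volume, centre uniform in the correspondingly eroded brain
ellipsoid, radius uniform in 5–9 voxels: a homogeneous +0.30 ball for LGG,
and for HGG a +0.35 rim around a −0.25 core of half the outer radius
(necrotic core with enhancing rim).  Default grid 64³ at 2 mm; default
dataset 60 volumes per class; fixed spec + seed reproduce bit-identical
volumes and manifests.

The phantoms deliberately omit anatomy, bias fields, multi-contrast
appearance and partial-volume effects, so passing desk-scale tests shows
that the pipeline and optimization behave correctly on separable
volumetric data — not that the models reach any particular accuracy on
real MRI.

## Desk-scale experiment sizes

CPU-scale runs keep the protocol structure intact (3 stratified repeats,
Adam, weight decay 1e−3, batch size 1, light augmentation, per-fold class
weights, final-epoch weights) and adapt three scale-dependent knobs:

* `base_width=4` (stage widths 4/8/16/32, 32 pooled features) — the
  width-reduced variant.  Narrower variants (width 2) train markedly less
  reliably: whether training escapes the early uniform-prediction plateau
  then depends on the luck of the initial filters;
* learning rate 1e−3, 19 epochs, tail averaging over the last 5 — at the
  full-scale 1e−5, a few thousand single-sample Adam steps move each
  parameter by ~1e−2 in total, far too little to fit anything at this
  scale, while 5e−3 and above destabilize batch-norm statistics and
  collapse training;
* dropout 0 instead of 0.3 — dropout noise scales inversely with head
  width: dropping 30% of a 32-feature pooled vector injects per-step
  gradient noise that empirically pins desk-scale training at the
  uniform-prediction plateau.  Full-width configurations keep the 0.3
  default; the separable phantom task needs no regularization.

On the default 60-per-class phantom dataset this configuration trains all
three folds in roughly 19 minutes on one CPU.  It separates healthy from
pathological phantoms perfectly and recovers tumour grade only partially:
observed pooled accuracy ≈ 0.81 and macro F1 ≈ 0.81, with the residual
errors almost entirely high-grade lesions read as low-grade.  The
high-grade cue (a small hypointense core inside an intensity-clipped
hyperintense lesion) is a genuinely second-order feature; at this width
and step budget its margin converges slowly, and single folds range from
0.74 to 1.00 depending on the initialization draw.  Exact settings live
in `tests/test_acceptance.py`.

## Numerical choices

* float32 parameters and activations in training; the loss and metric
  functions compute in float64.
* He fan-out initialization for convolutions, unit/zero batch-norm,
  uniform ±1/√fan_in for the head; every stream (init, shuffling,
  augmentation, dropout, phantom noise) is seeded through
  `numpy.random.SeedSequence`, so runs are bit-reproducible on a given
  platform.
* Sample (n−1) standard deviation over folds.
* Degenerate inputs: constant volumes are rejected by the percentile
  scaler; an empty resampling grid, an infeasible lesion radius, a class
  with fewer than two samples, and non-finite losses all raise immediately
  with context.

## Known limitations

* No GPU path; full-width training at realistic volume counts is out of
  reach on one CPU.
* Pretrained-weight *acquisition* is out of scope; `load_pretrained`
  implements only the transfer policy (copy everything except stem and
  head) between compatibly built networks.
* The phantom classes are separable from first-order intensity statistics;
  real-data difficulty (LGG vs HGG texture overlap, dataset bias between
  cohorts) is not modelled.
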