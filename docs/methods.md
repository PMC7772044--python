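# Methods

## The problem and the model

Benign/malignant discrimination of mammographic mass patches must cope with a
nuisance the acquisition process guarantees: the same tissue texture appears
at arbitrary orientations depending on body posture and imaging angle.  The
package combines two per-image representations designed around that nuisance
and a reduction step that fuses them compactly:

1. **Rotation-invariant texton block (288 dims).**  The image is standardized
   (zero mean, unit variance) and convolved with a 38-filter maximum-response
   bank: an edge filter G' = G_x cos θ + G_y sin θ and a bar filter
   G'' = G_xx cos²θ + G_yy sin²θ − 2 G_xy cos θ sin θ at 3 scales × 6
   orientations (36 anisotropic kernels), plus an isotropic Gaussian and a
   Laplacian of Gaussian.  Keeping only the per-pixel maximum over the 6
   orientations, per filter type and scale, collapses 38 responses to 8 maps;
   the collapsed stack is Weber contrast-normalized per pixel
   (r ← r · log(1 + L/0.03)/(L/0.03), L = ‖r‖₂).  Each of the 8 maps is then
   summarized by a rotation-invariant uniform local-binary-pattern (riu2)
   histogram on two sampling rings, (P=8, R=1) and (P=24, R=3), giving
   (8+2) + (24+2) = 36 bins per map and 8 × 36 = 288 features per image.
2. **Deep block (1024 dims).**  Any fixed-length per-image embedding satisfies
   the contract; pretrained CNN backbones plug in via a callable or an
   external command.  The built-in default is a frozen random-convolution
   network (3×{conv 3×3, ReLU, 2×2 average pool}, global average pooling, and
   a frozen linear projection to 1024).  It is *not* a trained feature
   extractor and is not presented as one; it supplies a deterministic,
   realistic, weakly informative high-dimensional block so the fusion and
   selection machinery is exercised end to end without any download.
3. **Fusion.**  *Direct fusion* concatenates the blocks (288 + 1024 = 1312)
   and classifies with a softmax head.  *Fusion after reduction* first ranks
   each block's features by random-forest out-of-bag permutation importance
   D_i = (1/M) Σ_m (A_m^oob − A_{m,i}^oob) — tree m's OOB accuracy drop when
   feature i is permuted within its OOB rows — then walks the ranking with
   sequential forward selection (SFS) under stratified 5-fold CV, keeping a
   candidate only if mean CV accuracy improves by at least a tolerance, and
   finally concatenates the two reduced blocks for an RBF-SVM.

Evaluation reports Acc = (TP+TN)/N, Sens = TP/(TP+FN), Spec = TN/(FP+TN)
with the malignant-like class (label 1) always positive, plus the ROC and its
trapezoidal area (identical to the Mann–Whitney rank statistic; asserted in
the tests to 1e-9).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| bank scales (σ_across, σ_along) | (1,3), (2,6), (4,12) | px | the standard maximum-response geometry; 3:1 elongation gives orientation selectivity |
| orientations | 6 over 180° | — | the standard bank; rotating the image by 90° permutes the set exactly |
| support | 49×49 | px | covers ±2σ of the largest kernel |
| Gaussian / LOG σ | 10 | px | standard isotropic channels of the same construction |
| edge rectification | abs before max | — | the edge kernel is antisymmetric; rectification stops contrast-inversion sign flips (switchable) |
| Weber normalization scale | 0.03 | response units | the standard contrast-normalization constant |
| LBP rings | (8,1), (24,3) | (count, px) | two-resolution riu2 whose bin count realizes exactly 36 dims per response |
| tie rule | s(x)=1 for x ≥ 0 | — | ties count as "above"; a tiny interpolation slack (1e-9·range) keeps exact ties stable under bilinear sampling |
| importance forest | M = 500 trees, √N features/split, unlimited depth | — | conventional defaults for permutation-importance stability |
| SFS | tolerance 1e-4, 100-tree forest as CV classifier, top-50 candidates | — | strict-positive improvement avoids float-noise acceptance; the candidate cap keeps the per-candidate 5-fold CV tractable and mirrors selecting only the head of the ranking |
| SVM | RBF, γ = scale heuristic, C tunable on a validation grid (ties → smallest C) | — | standard practice absent stronger guidance |
| softmax head | 1 affine layer, input dropout 0.5, full-batch SGD, lr 1e-3, 200 epochs | — | the minimal probabilistic head for the direct-fusion arm |
| CLAHE | clip 0.02, 8×8 tiles | — | standard contrast-limited equalization for radiography patches |
| split | 60/10/30, stratified, group-aware | — | augmented copies of one source never straddle a partition |

## The synthetic generator

Each patch is an oriented sinusoidal grating (class-specific frequency and
contrast) + Poisson-scattered Gaussian blobs (class-specific density) +
i.i.d. Gaussian noise, clipped to [0,1], presented at a global rotation drawn
by policy (`none`, `multiples_of_90`, `uniform_0_360`).  Default class
conditions: benign-like (freq 0.12 cyc/px, contrast 0.22, 1.0 blobs/10⁴ px,
noise σ 0.04) vs malignant-like (0.18, 0.45, 3.5, 0.04) — the malignant-like
class has the busier oriented micro-texture, with both a texton-visible cue
(frequency/contrast) and a blob-density cue the pooled deep block picks up,
so the two blocks carry partially disjoint signal.  Rotation by multiples of
90° uses exact grid rotation; other angles use bilinear resampling with
reflect padding on an enlarged canvas followed by a central crop, so border
artifacts cannot leak orientation information.

What it does *not* emulate: anatomy (mass margins, spiculation, parenchymal
background), detector physics, inter-patient variability, or label noise.
Two consequences for interpreting results: (i) classification on these
patches saturates — every classifier reaches ≈1.0 CV accuracy at the default
conditions, because each 96×96 patch carries tens of thousands of pixels of
clean texture statistics — so the pipeline comparisons demonstrate plumbing
correctness and the *no-harm* property of fusion (fused ≥ best single block),
not clinical performance; (ii) nothing here predicts accuracy on real
mammography.

## Numerical choices and degenerate inputs

* Convolution is FFT-based correlation on a reflect-padded image; output size
  equals input size.  Rotation-invariance checks at arbitrary angles exclude
  a margin of support//2; at 90° multiples the equality is global because
  reflect padding commutes with grid rotation.
* A numerically constant image (std ≤ 1e-12) is centered but not scaled
  during standardization; CLAHE returns constant images unchanged.
* LBP histograms exclude pixels within max(R) of the border from every ring
  and normalize the concatenated 36-bin vector to sum 1.
* Importance ties are broken by ascending feature index (stable sort); SFS
  always keeps the first candidate, so a selection is never empty for a
  non-empty block.
* The OOB bootstrap resamples until the out-of-bag set is non-empty (only
  relevant at very small n).
* All randomness flows from explicit integer seeds; repeated calls are
  bit-identical (asserted for the generator, the deep default backend, the
  reduction path and CV fold assignment).

## Measured rotation-invariance behavior

Quarter-turn invariance is exact: the orientation set is closed under 90°
rotation, grid rotation is exact, and the measured end-to-end texton
difference is 0.0 (tested at 1e-9).  At arbitrary angles the invariance is
approximate: on noisy gratings at the generator's class conditions the
texton cosine similarity between orientations is ≈0.84–0.98, worst for
axis-aligned versus mid-cell angle pairs.  The residual is not LBP (raw-image
riu2 histograms are rotation-stable to cosine 0.9999) and not orientation
count (12 or 18 orientations do not improve it); it is the local geometry of
the max-over-orientations map itself — a clean stripe pattern when the
carrier aligns with a filter, a flattened max-of-two-phases pattern between
filters — which the amplitude-blind LBP reads directly.  Channels carrying
only isotropic filtered noise are unaffected.  This is a property of the
maximum-response construction on narrowband oriented texture, mild on
broadband natural texture; the test suite asserts the exact 90° clause and
reports the measured arbitrary-angle similarity.

## Problem sizes

The end-to-end experiment (`ExperimentConfig`) defaults to 80 patches of
96×96, a 150-tree importance forest, a 50-tree SFS forest and top-25
candidates per block: a full run takes about a minute on one CPU and the
conclusions it supports (dimensional bookkeeping, determinism, no-harm
fusion) are insensitive to scale.  The structural checks use 300×300 patches
matching the intended patch geometry.

## Known limitations

* The default deep backend is untrained; with it, the deep block's
  discriminative power comes from generic contrast/activation statistics.
  Conclusions about *pretrained* CNN complementarity require plugging in a
  real backbone.
* Binary labels only; no multi-class support.
* Arbitrary-angle rotation invariance is approximate (see above).
* SFS evaluates candidates with a forest by default; the selected subset is
  mildly classifier-dependent.
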