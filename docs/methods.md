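# Methods

## Problem and model

Ovarian follicles appear in B-mode ultrasound as dark (anechoic) roughly
elliptical regions in brighter tissue. Segmenting them is hard for three
reasons: strong multiplicative speckle noise, blurred object boundaries, and
a variable number of follicles per image. `folliseg` implements an
encoder–decoder segmentation network whose training objective couples a
region term with an explicit boundary term, plus attention gates that let
the decoder suppress irrelevant tissue.

The model is a U-Net: per stage two 3×3 convolutions, instance
normalisation and ReLU; 2×2 max-pool downsampling with channel doubling;
2×2 transposed-convolution upsampling; a 1×1 head producing one mask logit
per pixel. Two optional components define the ablation axes:

* **Attention gates (AM).** Each skip connection is re-weighted by a
  per-pixel coefficient α ∈ (0, 1) computed by additive attention: the skip
  feature (1×1 conv, stride 2) and the coarser decoder feature (1×1 conv)
  are projected to a common width, summed, rectified, projected to one
  channel, squashed by a sigmoid and upsampled back to the skip resolution;
  the skip feature is multiplied by α. Gates are initialised *open*
  (final-projection bias +3, α ≈ 0.95): the gated network starts as the
  plain backbone and learns which regions to suppress, instead of starting
  with skips throttled to half strength by a random gate.
* **Edge information (EI).** A Canny operator — implemented from scratch as
  Sobel gradients → magnitude/angle → non-maximum suppression →
  double-threshold hysteresis — extracts the boundary of the ground-truth
  mask. On the prediction side, where Canny's thresholding would block
  gradients, the edge branch is the *soft edge*: the Sobel gradient
  magnitude of the predicted probability map, normalised to [0, 1]. The
  two edge maps are compared by a class-balanced cross-entropy
  (β = |Y⁻|/|Y| weighting the sparse edge class), and the training loss is

      L_joint = λ₁·L_mask + λ₂·L_edge,

  with L_mask the mean per-pixel binary cross-entropy (soft Dice available
  via config) and λ₁ = λ₂ = 1 by default.

### Edge-operator conventions

* `dx` is the horizontal (column-direction) derivative; kernels are applied
  as correlations with symmetric ("reflect") border padding, so constant
  images produce exactly zero gradients and outputs keep the input shape.
* The gradient angle is the two-argument arctangent of (dy, dx); non-maximum
  suppression quantises it to 0°/45°/90°/135° sectors. A pixel survives NMS
  iff its magnitude is strictly greater than the lower-index neighbour and
  at least as large as the higher-index neighbour along the quantised
  direction: single-pixel ridges survive unchanged, wider constant plateaus
  thin deterministically to their lowest-index pixel.
* Hysteresis uses 8-connectivity. Thresholds are absolute gradient
  magnitudes; the defaults are 10 % (low) and 20 % (high) of √20 ≈ 4.472,
  the largest Sobel magnitude attainable on a [0, 1] image (the maximum of
  a convex quadratic over the unit box, reached at a binary 3×3 patch and
  verified by brute force in the tests). The same constant normalises the
  soft edge, so its range is exactly [0, 1].
* Optional Gaussian pre-smoothing is off by default; the core pipeline
  starts at the Sobel stage.

### Numerical engine

No GPU framework is used: `folliseg.nn` is a small reverse-mode layer
library on numpy arrays (channels-last layout; im2col + BLAS matmuls for
convolutions; hand-written backward passes verified against central
differences in double precision by the test suite), with an Adam optimiser.
This keeps the package dependency-light and fully deterministic on CPU;
the price is that the clinical-scale protocol (below) is slow on one core,
which is why a scaled desk regime is bundled for testing.

## Phantom generator

The clinical images behind the method are not distributable, so the package
ships a speckle-phantom generator that emulates exactly the three stressors
above and provides exact ground truth:

1. smooth low-frequency tissue background around `tissue_level` (0.5),
   amplitude 0.05;
2. k ~ Uniform{1..6} ellipses with semi-axes drawn from `axis_range`,
   rejection-sampled so pairwise mask IoU ≤ 0.05 (distinct follicles are
   distinct anatomical objects; ≤ 100 retries, then the sample keeps the
   follicles placed so far);
3. ground-truth mask rasterised from the exact ellipse geometry, pixel
   centres at half-integer coordinates;
4. follicle interiors at `anechoic_level` (0.08), blended into tissue
   through a Gaussian blur of the mask (`boundary_blur_sigma` — the blurred
   edge);
5. multiplication by unit-mean gamma speckle, shape 3 by default (smaller
   shape = stronger noise; `None` disables it);
6. clipping to [0, 1].

The mask is deliberately the *pre-blur* geometry — the anatomical boundary
a clinician would trace — not the blurred image boundary. An optional
low-frequency radial perturbation of the ellipse outline is available
(`radial_perturbation`, off by default for testability).

What the phantoms do **not** model: point-spread functions, attenuation,
shadowing, fan-beam geometry, multi-organ context, inter-patient intensity
variation. Passing the phantom study therefore shows that the method learns
to segment noisy, blur-boundary, variable-count anechoic objects — it does
not certify clinical performance.

One property worth noting: because the boundary blur blends the mask
*symmetrically*, the gradient maximum — and hence the Canny localisation
after non-maximum suppression — stays centred on the true boundary at every
blur width; blur degrades boundary *contrast* (mean gradient magnitude on
the true boundary falls monotonically with σ), not Canny's mean edge
position. The degradation test asserts the contrast decline.

## Protocols

* **Clinical-scale defaults** (what the method is specified for): 256×512
  crops, depth-4/base-64 network, 300 epochs, Adam, lr 1e-4, batch 4.
* **Desk-scale regime** (`desk_phantom_config` / `desk_train_config`, used
  by the tests and the acceptance script): 64×128 phantoms with semi-axes
  3–15 px (the clinical 10–60 px scaled by the 4× linear downscale) and
  boundary blur 1 px; depth-2/base-4 network; 300/50/50 split, 15 epochs,
  batch 4, lr 1e-3. The learning rate is scaled up because the step budget
  is ~75× smaller than the clinical protocol's; speckle strength and
  intensity levels are unchanged.
* **Ablations** mirror the component study: `backbone`, `backbone+AM`,
  `backbone+EI`, `backbone+EI+AM`. All variants share bit-identical
  backbone initialisation and data order per seed (gate and edge-head
  parameters come from separate RNG streams), so differences are
  attributable to the components.
* **Model selection**: best validation Dice. **Inference binarisation**:
  0.5. **Aggregation**: unweighted mean of per-image scores (pooled-pixel
  aggregation available by flag). Degenerate images: both masks empty →
  all scores 1; exactly one empty → Dice = Jaccard = 0 and the undefined
  ratio (recall for empty GT, precision for empty SR) is reported as NaN
  and excluded from aggregation.
* The single-image overfit smoke test runs 200 Adam steps at lr 6e-3 — a
  rate suited to a 200-step budget rather than a full run — and checks the
  joint loss falls below 0.05.

## Numerical choices and edge cases

* Probabilities are clamped to [1e-7, 1 − 1e-7] before logarithms; the
  balanced edge loss accepts all-edge and no-edge labels (one term
  vanishes).
* Mask BCE is computed from logits via log-add-exp for stability.
* The soft edge's gradient is taken as 0 at exact zero-magnitude pixels.
* Max-pool ties route the gradient to the first position; instance norm
  uses ε = 1e-5 and behaves identically in training and inference.
* Initialisation is He-style from a seeded generator, except the 1×1
  classification head, whose drawn magnitudes are given alternating signs:
  the head reads nonnegative post-ReLU features, and at narrow widths a
  random draw with all weights of one sign pins the initial logit to one
  side of zero and can stall training for the whole step budget.
* Dataset splitting floors the train and val targets and gives the
  remainder to test (70/15/15 of 10 → 7/1/2), then assigns by a seeded
  permutation.
* Mask PNGs are strict 0/255; any other value raises instead of being
  thresholded silently.

## Known limitations

* The engine is CPU-only; the clinical-scale protocol is impractically slow
  on one core and is provided as configuration, not as a tested regime.
* The edge branch is parameter-free by default (soft edge of the predicted
  probabilities); a learned 1-conv edge head exists behind
  `learned_edge_head` but is not part of the tested ablations.
* Phantom realism is limited as described above; phantom defaults are
  plausible but uncalibrated against any published dataset statistics.
* Instance-level metrics (per-follicle counting, Hausdorff distance) are
  out of scope; evaluation is purely pixel-level.
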