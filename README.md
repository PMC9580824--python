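# folliseg

Edge-aware segmentation of ovarian follicles in B-mode ultrasound.

Follicle count and diameter are key quantities in reproductive medicine
(e.g. in diagnosing polycystic ovary syndrome), and both come from
segmenting the dark, fluid-filled — *anechoic* — follicles in ovarian
ultrasound images. Three properties of ultrasound make this hard: strong
multiplicative speckle noise, blurred object boundaries, and a variable
number of follicles per image. `folliseg` is for researchers who want a
fully reproducible, dependency-light implementation of an edge-supervised
segmentation network for this problem, together with a synthetic
speckle-phantom generator so every stage can be trained and tested without
clinical data.

## Method

The segmentation backbone is a U-Net with optional **attention gates (AM)**
on the skip connections: a per-pixel coefficient map α ∈ (0, 1), computed by
additive attention between the skip feature and the coarser decoder
feature, re-weights each skip so the decoder focuses on follicular regions.

The distinctive ingredient is **edge information (EI)**. A from-scratch
Canny operator (Sobel gradients → non-maximum suppression → double-threshold
hysteresis) extracts the boundary of the ground-truth mask; the prediction
side uses a differentiable *soft edge* — the normalised Sobel gradient
magnitude of the predicted probability map — so gradients can flow. The two
are compared by a class-balanced cross-entropy with β = |Y⁻|/|Y| weighting
the sparse edge class, and training minimises the joint loss

```
L_joint = λ₁ · L_mask + λ₂ · L_edge ,        λ₁ = λ₂ = 1 by default,
```

where `L_mask` is per-pixel binary cross-entropy. Evaluation reports the
standard pixel scores Recall = TP/(TP+FN), Precision = TP/(TP+FP),
Jaccard = |GT∩SR|/|GT∪SR| and Dice = 2|GT∩SR|/(|GT|+|SR|).

Everything runs on numpy: `folliseg.nn` is a small reverse-mode layer
library (convolutions via im2col + BLAS, hand-written backward passes
verified against finite differences) with an Adam optimiser. See
`docs/methods.md` for the full model description, phantom design,
conventions and limitations.

## Worked example

Generate 200 desk-scale phantoms (64×128, follicle semi-axes 3–15 px,
gamma speckle), split them 70/15/15, train the full model (edge loss +
attention) for 15 epochs, and evaluate on the held-out test split:

```
$ folliseg make-phantoms --out demo --n 200 --seed 7
wrote 200 samples to demo
$ folliseg split demo --ratios 0.7,0.15,0.15 --seed 0
split sizes: {'train': 140, 'val': 30, 'test': 30}
$ folliseg train demo --out demo-run --variant backbone+EI+AM --seed 0
best val Dice: 0.9003
checkpoint: demo-run/checkpoint.npz
$ folliseg evaluate demo-run/checkpoint.npz demo
Recall    0.9187
Precision 0.8325
Jaccard   0.7630
Dice      0.8453
```

The four numbers are mean per-image scores on the 30 test phantoms: the
model recovers ~92 % of true follicle pixels (recall) at ~83 % precision;
Dice 0.85 means predicted and true masks overlap by 85 % of their mean
size. More training data pushes this further — the bundled study below
trains on 300 images and reaches test Dice ≈ 0.94.

The same workflow is available from Python (`folliseg.pipeline`), and
`folliseg ablate` reproduces the component study
(`backbone` / `backbone+AM` / `backbone+EI+AM`) with mean ± sd per metric
over several seeds.

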