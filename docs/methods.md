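# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish about real histopathology data.

## Problem setting

Clinical pre-screening of histopathology slides is recall-critical: a
missed metastatic region is far costlier than a false alarm a pathologist
can dismiss. The package therefore implements a segmentation framework in
which every component is biased toward sensitivity — the loss penalises
false negatives more than false positives, model selection during
training uses validation recall, the weak-label fusion is a union, and
the human-in-the-loop stage spends its budget on the most uncertain
samples of every organ class.

## Network

The model is a symmetric encoder–decoder with seven stages of channel
widths (64, 128, 256, 512, 256, 128, 64) at the published configuration:
four encoder stages (the 512-channel stage is the bottleneck; there is no
separate wider bottleneck) and three decoder stages with 2×2 transposed-
convolution upsampling and skip concatenation. Each stage is a double
3×3 convolution with ReLU. Three mechanisms can be attached per stage:

- **Squeeze-and-excitation (SE)**: global average pool → FC(C → C/r) →
  ReLU → FC(→ C) → sigmoid, multiplying each channel by a weight in
  (0, 1). Reduction ratio r = 16 (the standard choice; smaller widths in
  tests use smaller r so the bottleneck stays ≥ 1).
- **FiLM organ conditioning**: an organ label y ∈ {1..K} indexes a
  learnable K×d embedding table (d = 32). Per stage, independent linear
  maps produce γ = σ(W_γ z + b_γ) and β = W_β z + b_β with C_s outputs,
  and the features are transformed channel-wise as (1 + γ)·F + β. The
  sigmoid keeps the scale inside (1, 2). The FiLM linear maps initialise
  at zero, so an untrained network is organ-agnostic (scale exactly 1.5,
  shift 0) and conditioning is learned, not imposed.
- **Edge head** (on the last decoder stage's 64-channel features): a STEM
  of two 3×3 convolutions + ReLU, three parallel 3×3 dilated convolutions
  (dilation 1, 2, 3, padding = dilation), channel concatenation, then two
  1×1 convolutions and a sigmoid. Internal widths are 64→32→32 (STEM),
  32→32 per branch and 96→32→1 for the fusion; these widths are this
  package's choice, as is the stage-internal order convolutions → SE →
  FiLM (conditioning acts on recalibrated channels).

Batch normalisation is deliberately omitted from the stage blocks: its
batch-statistics coupling breaks the bit-level determinism contracts the
test suite enforces, and the networks trained here converge without it.
The default-width model has ~7.9 M learnable parameters; published
descriptions of this family of models leave the internal widths of the
auxiliary heads open, so parameter counts are reported but not asserted.

All tensor work runs on a small reverse-mode automatic-differentiation
engine over float64 numpy arrays (`clinsegnet.nn`): convolutions are
evaluated as nine shifted channel contractions (einsum), max-pooling
routes gradients through argmax, and every primitive is verified against
central finite differences in the test suite.

## Losses

- BCE: mean over all pixels of −[y log p + (1−y) log(1−p)], probabilities
  clamped at 1e−7.
- Tversky: 1 − (TP+ε)/(TP + α·FP + β·FN + ε) on soft counts pooled over
  the whole batch (TP = Σpy, FP = Σp(1−y), FN = Σ(1−p)y), with α = 0.3,
  β = 0.7 and ε = 1e−6 (the smoothing value is this package's choice).
  β > α makes the gradient at a missed positive steeper than at a
  symmetric false positive — the mechanical recall bias, asserted by a
  gradient test.
- HistoLoss = 0.3·BCE + 0.7·Tversky.
- Edge supervision: BCE between the edge head's output and a
  morphological-gradient target, dilation(X) − erosion(X) with a 3×3
  structuring element realised as max-pooling (erosion as
  1 − maxpool(1 − X)). Border rule: out-of-frame counts as background for
  the dilation and foreground for the erosion, so masks touching the
  frame produce no spurious border edge and an all-ones mask has no edge.
- Total = 1.0·HistoLoss + 0.4·edge BCE. Whether the pixel means pool per
  image or per batch is not canonically fixed; batch pooling was chosen
  and is what the formulas above describe.

## Training and model selection

Adam, lr 5e−4, batch size 8, up to 50 epochs, inputs resized to 224×224
(bilinear for images, nearest for masks so they stay binary). After every
epoch the model is evaluated on the held-out split at threshold 0.5 and
the checkpoint with the highest validation recall is kept. No third
validation split is carved out — the test split doubles as the selection
set, a documented caveat of the small-data regime this mirrors.

## Offline human-in-the-loop stage

1. Predict probability maps for the pool (by default the training pool).
2. Score each sample by mean per-pixel binary entropy (natural log, so
   scores lie in [0, ln 2]; the base only rescales and never reorders).
3. Per organ class, select the top-k most uncertain samples with
   k = max(min_per_class, round(0.30·n)), capped at the class size;
   round-half-up and id-ordered tie-breaking make selection deterministic
   and order-independent.
4. Fine-tune with only decoder stages 6–7 (their up-convolutions,
   convolution blocks, SE and FiLM modules) and the output 1×1
   convolution unfrozen: Adam lr 2e−4, weight decay 1e−2, batch size 8,
   8 epochs, one-cycle schedule, EMA of the unfrozen weights
   (decay 0.999, this package's value) written back at the end.
5. Re-evaluate and report per-organ recall before/after.

The freeze contract is enforced by hashing: every frozen tensor is
bit-identical after fine-tuning. With few optimisation steps the EMA
keeps the fine-tuned weights close to their starting point — that is the
intended conservatism of the stage, which targets stability rather than
large metric movements.

## Weak-label generation

Paired H&E / Melan-A IHC regions of interest are processed as: rigid
alignment of the IHC onto the H&E (rotation about the image centre then
translation; bilinear resampling, white background fill, nearest-
neighbour for any mask) → 512×512 sliding-window patches at stride 256
over the overlap (windows beyond the stride lattice are dropped, so a
2100×1500 ROI yields exactly 7×4 = 28 patches) → two candidate DAB masks
per patch → logical-OR fusion.

- HSV candidate: keep pixels with hue in [15°, 45°], not in the blue
  band [180°, 260°], saturation ≥ 0.15; then opening/closing with
  radius-2 disks and removal of components smaller than 64 px.
- HED candidate: Ruifrok–Johnston colour deconvolution → DAB channel →
  Gaussian smoothing (σ = 2 px) → Otsu threshold floored at a minimum
  DAB optical density of 0.05 (Otsu always splits the histogram, so on a
  chromogen-free patch it would threshold pure background noise; the
  floor keeps such patches empty) → the same morphological clean-up plus
  small-hole filling. A constant DAB channel (Otsu undefined) yields an
  empty mask with a warning.

No canonical thresholds exist for this step; the defaults above are the
package's calibration, chosen once to satisfy the synthetic recovery
property (pooled pixel recall ≥ 0.90 and Dice ≥ 0.85 against exact
ground truth), and all of them are exposed in configuration. Union
fusion makes the weak label recall-biased by construction.

## Synthetic data generator

The generator emulates exactly the structure the pipeline assumes:
blob-like lesions (unions of ellipses with low-frequency radial
perturbation, giving irregular borders with pixel-exact ground truth,
coverage kept in 1–50%), a haematoxylin-blue textured background, a DAB
signal whose hue lies strictly inside the configured band and whose HED
DAB channel separates from background by more than two standard
deviations, per-organ texture/intensity styles derived deterministically
from the organ name, faint lesion contrast in the pseudo-H&E rendering,
and paired ROIs displaced by the exact inverse of a known rigid
transform. Randomness is keyed by (seed, organ, id), so generation is
bit-reproducible and order-independent.

What it does **not** model: nucleus-level instance structure, stain
variability across scanners and batches, inflammatory infiltration,
necrosis, out-of-focus regions, or any appearance overlap between lesion
and background colour. Passing the synthetic suites therefore
establishes that the algorithms are implemented correctly and behave as
designed under their stated assumptions — not that the trained models
would reach any particular accuracy on clinical material.

## Problem sizes used in the tests

The published training conditions (224×224 inputs, 64–512 channels,
50 epochs, thousands of images) are far beyond what a test suite should
spend; the suites therefore run the same architecture at reduced width
and resolution, a choice documented here once: the end-to-end training
check uses 48 images (3 organs × 16) at 48×48 with stage widths
(6, 12, 24, 48, 24, 12, 6) for 30 epochs; the augmentation count check
runs the full 472 source images at 128×128; the weak-label recovery
check uses the full-size 2100×1500 ROI. The default configuration keeps
the published values throughout.

## Known limitations

- Recall-based checkpoint selection has a degenerate attractor: an early,
  barely-trained model that predicts nearly everything positive scores a
  near-perfect recall and can be kept as the "best" checkpoint. This is
  inherent to single-metric recall selection; `selection_metric` is
  configurable (e.g. dice) for analyses where that behaviour is harmful,
  and the default remains recall to match the framework's stated
  priority.

- CPU-only float64 execution: training at the published scale is not
  practical with this engine; it exists to make the algorithms fully
  testable and reproducible.
- The HITL stage simulates expert correction by re-using ground-truth
  labels on the selected subset; no real annotation ingestion exists.
- Automatic registration of stain pairs is out of scope (alignment
  parameters are taken as given), as is stain normalisation.
- Published aggregate benchmark results require non-public clinical data
  and GPU-scale training and are not reproduced; only the closed-form
  statistics derived from printed values are recomputed.
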