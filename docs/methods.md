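# Methods

## Model

The segmentation network is a standard U-Net. The contracting path has
`encoder_depth` stages; stage *i* applies two 3×3 same-padded convolutions
with ReLU at width `base_width·2^i`, then 2×2 max-pooling. A double-conv
bottleneck at width `base_width·2^depth` is followed by the expanding path:
nearest-neighbour ×2 upsampling, a 3×3 convolution halving the channel
count, concatenation with the same-resolution encoder features (skip
connection), and another double convolution. A 1×1 convolution projects to
six class scores and a per-pixel softmax yields class probabilities.
Weights are He-normal initialized from a seeded generator; biases start at
zero. Inputs are 8-bit RGB tiles scaled by 1/255. Tile sides must be
divisible by `2^encoder_depth`.

Forward and backward passes are written directly in numpy (im2col/col2im
convolutions, argmax-routed pooling gradients, block-sum upsampling
gradients) rather than through an autodiff framework; the layer gradients
and the end-to-end parameter gradients are pinned against central finite
differences in the test suite. Activations are float32; the finite-
difference tests run the network in float64 and jitter biases first,
because zero-initialized biases place dead-ReLU pixels exactly on the
kink where the subgradient and a central difference legitimately disagree.

## Training objective

`total = focal + dice`, selectable as `focal`, `dice` or `focal+dice`.

- **Focal loss**: per pixel, `−Σ_c gt_c · α (1−pr_c)^γ ln(pr_c + ε)`,
  summed over classes and averaged over pixels and batch. Defaults
  α = 0.25 (class-balance factor), γ = 2 (focusing exponent). γ = 0 with
  α = 1 reduces exactly to categorical cross-entropy. α is a single scalar
  applied to all classes.
- **Dice loss (F-β form)**: per class, soft precision `P = Σ gt·pr / Σ pr`
  and soft recall `R = Σ gt·pr / Σ gt` are computed from probability mass
  over the whole batch, and the loss is `1 − (1+β²)·P·R / (β²·P + R + ε)`,
  averaged over the classes present in the ground truth. Default β = 1
  (equal precision/recall weighting). The denominator is the standard F-β
  combination `β²·P + R`; with a multiplicative denominator the expression
  would be constant in the prediction and useless as a loss. Classes absent
  from the reference batch are excluded rather than scored 0, since a small
  batch can easily lack a minority class.
- ε = 1e-7 smooths logs and ratios. Both losses ship analytic gradients
  with respect to the probabilities; the softmax Jacobian converts them to
  logit gradients.

Reduction order (focal: sum over classes, mean over pixels and batch;
dice: mean over present classes) is fixed and documented because it sets
the relative scale of the two gradients.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999), default learning rate 1e-3,
default batch size 8, default 100 epochs — the batch/epoch defaults mirror
the conventional setup for this kind of tiled training; the desk-scale
tests use far fewer epochs. Training is reproducible given the seed and a
single BLAS thread.

## Evaluation

All metrics derive from one C×C confusion matrix (rows: reference,
columns: prediction). OA = trace/total; per-class IoU = TP/(TP+FP+FN);
per-class F1 = 2TP/(2TP+FP+FN) on hard counts. The identity
F1 = 2·IoU/(1+IoU) holds exactly and is used as a cross-check between the
two code paths. Macro means are unweighted over defined classes; a class
absent from both masks has an empty union and is flagged NaN, not counted
as zero. Because aggregation conventions for an "all classes" F1 differ
between published tables, a micro-averaged F1 (globally pooled counts,
which for single-label pixels equals OA) is reported alongside the macro
mean. Hard maps are per-pixel argmax of the probability stack; ties break
toward the lowest class index, deterministically.

## Ensemble

The ensemble probability is the weighted per-pixel sum of member
probability stacks, renormalized by the weight sum; the hard map is its
argmax. Weights are non-negative and deliberately not constrained to sum
to one — renormalization absorbs the scale, and scaling all weights by a
positive constant leaves both the normalized probabilities and the hard
map unchanged. The weight vector is found by exhaustive search over the
grid `{0, step, …, 1}^N` (default step 0.1), excluding the all-zero
vector, scoring each candidate's hard map against a held-out reference by
macro mean IoU (OA and macro F1 are selectable alternatives). The search
set must be held out from training: weights fitted on training pixels
would inherit member overfitting. Unit vectors lie on the grid, so the
result never scores below the best single member; among tied maximizers
the lexicographically smallest vector is returned (the first one visited,
since candidates are enumerated in lexicographic order). Per-class
weights, stacking and gradient-based weight fitting are out of scope.

## Synthetic scenes

`SceneSpec`/`generate_scene` produce co-registered image/label pairs with
the structure the pipeline assumes:

- **Patch geometry.** Aquaculture is pasted first as rectangles on a
  jittered grid inside a randomly placed zone (pond cells ≈ 1/12 of the
  short scene side, 70% fill). Remaining pixels are ranked by a Gaussian
  random field smoothed with σ = `texture_scale` (default 16 px) and split
  at the renormalized target quantiles, which makes realized class
  fractions near-exact. A sinuous river — a smoothed random walk spanning
  the full width, dilated to at most 3% of the scene — is overlaid last,
  so the overlay error stays well inside the ±0.10 fraction tolerance the
  generator guarantees for classes with target ≥ 0.05.
- **Default fractions** (0.10, 0.10, 0.05, 0.30, 0.05, 0.40) put the three
  mangrove classes jointly at ~25% of the area, with aquaculture and open
  water dominating the remainder, as in a delta land-cover scene.
- **Radiometry.** Pixel = per-class mean color + i.i.d. Gaussian noise
  (default sd 10), rounded and clipped to [0, 255]. Default class colors
  follow the rendering legend (dark blue, navy blue, light blue, green,
  orange, brown). Near 0 or 255 the clipping biases class means; the
  color-consistency test therefore uses interior colors.
- A fraction of exactly 1 yields a constant mask (no structure overlays).

`perturb_labels` reassigns exactly `round(rate·N)` pixels to a uniformly
random *different* class, giving controllable imperfect "predictions"
whose OA against the original is exactly `1 − round(rate·N)/N`.

What the generator does **not** emulate: sensor radiometry and atmosphere,
within-class spectral gradients and texture (classes differ only in mean
color), mixed pixels at boundaries, georeferencing beyond an affine
pass-through, and spatial autocorrelation between tiles of the kind that
makes per-tile random splits optimistic on real scenes. Passing tests
therefore demonstrate that the machinery is correct and that the training
loop can recover a color-separable scene — not that the accuracy figures
transfer to real imagery.

## Pipeline and problem sizes

`run_pipeline` chains generate → tile → train members → predict →
ensemble-search → evaluate → render, persisting every intermediate and a
manifest of seeds and content hashes; member training seeds derive from
the global seed plus the member index. Evaluation and the weight search
both use the validation tiles.

The demo configuration uses a 256×256 scene, 64-px tiles augmented to 60,
a 75:25 split, and three members of different depth/width (depth 3/width
12, depth 2/width 8, depth 3/width 16) trained 8 epochs — sizes chosen so
the whole run completes in a few minutes on one CPU while still showing a
genuine ensemble gain. The training-recovery benchmark uses 200 64×64
tiles from a 960×896 scene and a depth-3, width-8 U-Net for 10 epochs,
which reliably exceeds 0.8 validation mean IoU on the default scenes.

## Design decisions

- Tiles are cut on a non-overlapping grid and partial edge tiles are
  dropped, not padded — padding would distort class statistics.
- Augmentation is restricted to the eight dihedral transforms: they are
  label-preserving and interpolation-free.
- The split is per-tile and uniformly random; the spatial-leakage caveat
  above is documented rather than solved.
- Encoder backbones are configuration (depth/width presets), not
  pretrained networks; ensemble logic is architecture-agnostic.
- Raster I/O uses TIFF (tifffile) and PNG (Pillow); the label legend
  travels as a JSON sidecar; color→index encoding requires exact legend
  colors and reports any unmatched colors with pixel counts.

## Limitations

Training at realistic scene sizes is out of reach for a numpy
implementation — the package targets method correctness at desk scale.
Probability maps are float32; stitched maps flag uncovered pixels as NaN
and refuse overlapping tiles rather than blending. The ensemble weight
search is exponential in the member count (11^N candidates at step 0.1)
and is intended for the small member counts typical of soft-voting
ensembles.
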