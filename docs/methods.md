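# Methods

`vemseg` segments nuclei and nucleoli in volume electron microscopy (vEM)
stacks when only a small, evenly-spaced subset of slices carries manual
labels. This note documents the model and training procedure, the synthetic
data the package is validated on, the numerical choices, and the limits of
what the desk-scale experiments show.

## Problem setting

A FIB-SEM stack is a Z-series of large grayscale slices (in production data,
thousands of pixels per side; hundreds of slices). Manual annotation of a
full stack takes weeks to months, so the practical regime is *sparse
annotation*: `n_train` slices (7–25, roughly 0.3–3% of a stack) are labeled
and the model must segment the rest. Two binary structures are handled, one
model per structure: nuclei (large, ~5–30% of voxels) and nucleoli (small
bodies inside nuclei, well under 2% of voxels — a severe class imbalance).

## Data pipeline

* **Slice selection.** Training slices sit at centered quantiles,
  `i_k = floor((k + 0.5) · n_slices / n_train)`, so the gap between
  consecutive picks varies by at most one slice and the volume ends sit half
  a gap from the outermost picks. An endpoint-inclusive alternative is a
  config option (`slice_spacing: endpoint`).
* **Context tiling.** A crop is a `context_size`² window block-averaged down
  to `out_size`², giving the network a wide field of view at reduced
  resolution (production geometry 2048 → 512, factor 4; the desk-scale
  default here is 96 → 48, factor 2). Label windows are downsampled by block
  mean and thresholded at 0.5, ties counting as foreground. Windows reaching
  past the image border are reflect-padded.
* **Foreground guarantee.** Uniform crops on a nucleolus mask are almost
  always empty and models collapse to background. The sampler therefore
  guarantees a configured fraction of foreground-containing crops (default
  0.99): a fixed quota of each batch is re-drawn, up to 50 retries, centered
  with jitter on a random foreground pixel of a random foreground-bearing
  labeled slice. The quota is deterministic per batch (not per-item
  Bernoulli) so the realized fraction cannot fall below the target by
  sampling noise.
* **Augmentation.** Each crop independently receives one of the 8 symmetries
  of the square (right-angle rotations and mirrored versions), applied
  identically to image and label. No interpolation is involved, so labels
  stay exact and foreground counts are invariant.

## Architectures

Two encoder–decoder families are provided as size-parameterized builders on
a small numpy-based automatic-differentiation engine written for this
package (reverse-mode tape; im2col convolutions; fused batch norm; Adam).
There is no GPU path; the tested regime is deliberately small
(`base_width 8, depth 3` ≈ 43k parameters), and gradients of every primitive
are verified against finite differences in the test suite.

* **Residual U-Net** — residual blocks at every scale, strided-convolution
  downsampling, nearest-neighbour upsampling with skip concatenation, and a
  two-channel softmax head (background/structure). Softmax with per-pixel
  argmax, rather than a single sigmoid logit, matches the pseudo-label
  formulation below; ties argmax to background.
* **UNet++** — dense convolution blocks on the skip connections; with deep
  supervision every decoder branch gets its own head, the training loss
  averages the per-branch Dice losses, and the reported confidence map is
  the arithmetic mean of the branch confidences.

Batch normalization uses batch statistics during training and running
averages in evaluation mode; inference always runs in evaluation mode, so
tiled predictions are deterministic.

## Losses

**Soft Dice.** For a binary target `y` and foreground confidence `p`,

    DL(y, p) = 1 − (2·Σ y·p + ε) / (Σ y + Σ p + ε),      ε = 1 by default.

The smoothing term defines the empty-target/empty-prediction case as perfect
and stabilizes early training; ε is config-exposed. The loss is computed per
crop and averaged over the batch.

**Cross pseudo supervision (CPS).** Two networks of the same architecture,
differing only in initialization seed, are trained in parallel. On a batch of
(mostly unlabeled) crops each network's per-pixel argmax — its pseudo-label
map, treated as a constant (stop-gradient) — becomes a hard Dice target for
the *other* network's foreground confidence:

    L_cps = mean over crops of [ DL(ŷ₂, p₁) + DL(ŷ₁, p₂) ].

The per-pixel cross-entropy of the original CPS formulation is replaced by
the same soft Dice loss used for supervision, evaluated per crop over all
pixels; this keeps the training signal aligned with the evaluation metric
under class imbalance. The total objective per step is

    L = DL(labels, net1) + DL(labels, net2) + λ(step) · L_cps,

optimized by one Adam update per network per step. λ ramps up linearly from
0 to 1 over `warmup_steps` (default 400 at desk scale — the first 40% of
training, the "first epochs" regime in which learning must be driven by the
labeled slices: cross supervision should reach full weight only once the
pair's pseudo-labels are reliable);
while λ = 0 the CPS term is skipped entirely, which also makes the
`lambda_max = 0` configuration *exactly* equivalent to two independent
supervised runs (asserted in the tests).

**CPS batch composition.** CPS crops are drawn from the whole stack, so
under sparse annotation the batch is dominated by unlabeled slices. At least
`cps_foreground_fraction` (default 0.5) of the batch must contain the
structure: after warm-up the check uses the first network's current
pseudo-labels (rejection with a small redraw cap, falling back to
true-foreground crops from labeled slices when rejection cannot satisfy a
very sparse structure); during warm-up, when pseudo-labels are still
meaningless, the guaranteed share is drawn from labeled slices directly.

**CutMix.** With CutMix enabled (default for CPS), crops are mixed pairwise
(item *i* with item *B−1−i*): a rectangle whose area ratio is uniform on
(0, 1) — CutMix's Beta(1,1) — is pasted from one crop into the other. The
rectangle is placed uniformly among positions where it fits entirely inside
the crop, which preserves the drawn area ratio exactly (clipping a
uniformly-centered box would bias the realized area downward). Pseudo-labels
for a mixed crop are assembled from the pseudo-labels of the two *unmixed*
crops with the same rectangle mask, then compared against the networks'
confidences on the mixed input.

## Inference

Each slice is tiled on a fixed overlapping grid (stride = half a context
window, with a final anchor flush against the border), forwarded in
evaluation mode, and the foreground confidences are bilinearly upsampled to
native resolution and averaged in the overlaps. Bilinear (not
nearest-neighbour) upsampling of confidences recovers sub-block boundary
precision lost to the context downsampling. The binary prediction is
`confidence > 0.5`, ties going to background; a uniform-confidence network
therefore predicts pure background. By default the first network of a CPS
pair is used; a test-time symmetrization wrapper (averaging confidences over
dihedral transforms) exists but is off by default.

## Evaluation

* **3D Dice** — Dice of the flattened volumes; reflects the captured
  fraction of the structure.
* **Average Dice** — mean of per-slice Dice scores; biased toward slices
  with little foreground (a single bad sparse slice can halve it while the
  3D score barely moves — the two-slice construction in the tests
  demonstrates 3D = 0.9901 vs average = 0.5).
* Both-empty masks score 1 by convention (needed for background-only slices
  in the per-slice average; a config option skips empty-target slices
  instead).
* **Ranking.** A model × setting grid of Dice scores is summarized by mean,
  standard deviation (population formula by default; `ddof` exposed) and
  average rank (1 = best, ties share the mean of tied ranks). Applied to the
  bundled published benchmark grid, the UNet++ mean reproduces the printed
  0.9270 summary cell, and the semi-supervised UNet++-CutMix row leads the
  full grid.

## Synthetic volumes

Real vEM stacks are access-restricted, so the pipeline is validated on
generated volumes with analytic ground truth. Shapes are axis-aligned
ellipsoids; a voxel is foreground iff its center lies inside the ellipsoid
(making counts brute-force checkable); nucleoli are rasterized strictly
inside their nucleus. Intensity = per-structure gray level + smoothed-noise
texture inside nuclei + global Gaussian noise, clipped to [0, 1]. Identical
seeds give bit-identical volumes.

Two presets define the study conditions:

* **default** — well-separated gray levels (0.25 / 0.60 / 0.85, noise sd
  0.05), isotropic nuclei. An easy, unambiguous condition used for
  convergence and inference tests.
* **heterogeneous** — the hard condition on a 64 × 192 × 192 stack:
  12 nuclei flattened along z (z-radius 4–10 voxels vs 14–24 in-plane,
  cut by the stack ends like cells in real tissue), so with 7 labeled slices
  (gap ≈ 9) some nuclei barely or never intersect a labeled slice;
  per-nucleus gray levels (jitter ±0.16 around 0.50 against background 0.32)
  make the dimmest instances nearly undetectable by intensity alone; each
  nucleus carries its own texture amplitude and correlation length, so
  recognizing an instance is learnable from its labeled slices but does not
  transfer to unseen instances; and nucleolus gray values are jittered down
  to overlap the nucleus level. These ingredients reproduce, at desk scale,
  the characteristic failure mode of purely supervised sparse training —
  per-slice Dice peaks at the labeled slices and dips on dissimilar slices —
  and give the semi-supervised regularization something real to correct: in
  the bundled end-to-end experiment the CPS pair's training-slice vs
  held-out gap is consistently smaller than the supervised baseline's,
  although at this scale its held-out 3D Dice runs a few thousandths below
  the baseline (the cross-supervision term injects pseudo-label boundary
  noise that a 1000-step, small-batch run never amortizes).

What the synthetic volumes do *not* emulate: real SEM image formation
(charging, curtaining, anisotropic point-spread), membranes and other
organelles, irregular (non-ellipsoidal) morphology, and production image
sizes. Passing the end-to-end tests shows the training machinery behaves as
designed under the stated conditions, not that the small networks match
published accuracy on real tissue volumes.

## Desk-scale experiment sizes

All end-to-end checks run on one CPU with the numpy engine, which sets the
problem sizes used by the tests and the acceptance script: volume
64 × 192 × 192, 7 labeled slices, context 96 → 48 crops, ResUNet
`base_width 8 / depth 3`, batch 2 (labeled) + 2 (CPS), 1000 Adam steps at
learning rate 1e-3, warm-up 400 steps, λ = 1. The production-scale geometry
(2048 → 512 tiles, millions of parameters, multi-day GPU training) is
reachable through the same configs but is not the tested regime.

## Numerical and design choices

* ε = 1 in all Dice losses (config-exposed); pseudo-label ties and
  prediction ties resolve to background — conservative for sparse
  foreground.
* Per-volume min–max intensity normalization (per-slice as a config
  option); a degenerate range (max = min) maps to zeros with a warning.
* Optimizer settings (Adam, lr 1e-3, constant schedule) and batch sizes are
  not prescribed by the method and are config-exposed and logged.
* The two CPS networks share architecture and differ only by initialization
  seed; heterogeneous pairs are out of scope.
* Random anchors for training tiles; the inference grid is fixed.
* All randomness flows from explicit seeded generators: model initialization
  from `seed`, per-network data streams from `[seed, 101]`, the CPS stream
  from `[seed, 202]`. A saved training state (networks, optimizers, RNG
  states, log) resumes bit-compatibly at the logged-metric level.

## Known limitations

* The numpy engine is single-threaded and ~2 orders of magnitude slower
  than a GPU framework; production-size training is out of reach.
* Nearest-neighbour upsampling inside the decoders (not transposed
  convolution) and the small widths bound achievable boundary precision.
* The CPS foreground check on unlabeled crops trusts current pseudo-labels;
  for extremely sparse structures early after warm-up it can under-fill the
  quota until the fallback to labeled crops engages.
* Dice comparisons between training arms at desk scale carry seed-to-seed
  noise of roughly ±0.005–0.01; the end-to-end checks therefore use medians
  over three seeds.
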