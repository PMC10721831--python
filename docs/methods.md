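# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `phasepaint`. It is written for a reader who wants to know
exactly what the package computes and why each default is what it is.

## Problem setting

Phase-contrast microscopy is cheap and live-cell compatible but carries no
molecular labels. For 2.5D intestinal organoids — organoids grown on a soft
hydrogel so their crypt-villus architecture lies in a near-planar, imageable
presentation — the phenotypes of interest (crypt formation, stem-cell
abundance, secretory-cell abundance) are normally read out from fluorescent
stains: a nuclear stain, an LGR5 reporter marking intestinal stem cells in
crypts, and the UEA-I lectin marking secretory cells as dot-like puncta.
`phasepaint` learns the mapping from a phase image to each fluorescent
channel ("virtual painting") and then quantifies phenotypes from the virtual
stains.

The pipeline treats virtual painting as *segmentation*: fluorescent targets
are binarized into masks, a per-pixel probability is predicted for each
channel, and the color image is reconstituted by multiplying probability by
the display intensity (probability 1.0 in the nuclei channel is pure blue,
(0, 0, 255)). This sidesteps adversarial image synthesis entirely; no GAN
discriminator is involved anywhere.

## Pre-processing and tiling

Full frames (nominally 1536x1024) are cut into square tiles with 50 %
overlap (tile 256, stride 128 at full scale; tile 64, stride 32 at desk
scale). When a dimension is not a multiple of the stride, a final origin is
placed flush with the image edge, so coverage is complete without
introducing padded synthetic pixels. At inference, overlapping tile
predictions are merged by their unweighted mean — the unique linear rule for
which merge after extract is exactly the identity — with elementwise maximum
available as an option. Fluorescent targets are binarized by thresholding;
the threshold defaults to Otsu's method per channel (a data-driven stand-in
for a background-derived level) and can be overridden with an explicit
value.

## The generator network

One single-channel model is trained per fluorescent channel (a shared-trunk
multi-head variant is available through `NetworkConfig.out_channels`). The
architecture is an attention U-Net:

* **Encoder** — a stack of ResNeXt-style bottleneck blocks, one per stage,
  each entered at stride 2: conv1x1 / norm / ReLU, grouped conv3x3 / norm /
  ReLU, a squeeze-and-excitation (SE) channel gate, conv1x1 / norm, plus a
  projection shortcut (three convolutions, three normalizations, two ReLUs,
  SE between the convolutional layers). Stage *s* halves the resolution and
  doubles the channel count (`base_channels * 2^s`).
* **Decoder** — one block per stage: nearest 2x upsampling, concatenation of
  the matching encoder features (the deepest-to-shallowest skip pattern; the
  final block has no skip), two conv3x3 / norm / ReLU pairs, and a
  concurrent spatial and channel squeeze-and-excitation (scSE) gate. The
  spatial branch pools along the channel axis and maps each location through
  a two-layer 1x1-convolution MLP to a per-pixel sigmoid gate; the two gated
  tensors are combined by elementwise maximum (addition optional).
* **Head** — hypercolumn fusion: every decoder output is resized to full
  resolution, concatenated, passed through dropout (p = 0.5) and a 1x1
  convolution, and squashed by a sigmoid to per-pixel probabilities.

Weights are He-normal initialized from a seeded generator recorded in the
config, so model construction is reproducible. Two presets exist: the
desk-scale default (4 stages, 16 base channels, cardinality 4) that trains
in minutes on one CPU, and a full-scale preset (5 stages, 64 base channels,
cardinality 32, SE reduction 16) matching an SE-ResNeXt50-width encoder.
Normalization is batch normalization by default, switching to group
normalization when the batch size drops below 8 (batch statistics degenerate
in tiny batches).

### Compute backend

The network runs on a small tape-based reverse-mode automatic
differentiation engine over NumPy arrays (`phasepaint.nn`): grouped/dilated
2-D convolution via im2col with batched BLAS contractions, batch/group
normalization with gradients flowing through the statistics, SE gating,
nearest upsampling, dropout, and an Adam optimizer. Gradient correctness is
pinned by central-difference checks in the test suite rather than assumed.
All arithmetic runs in float32 by default (Python scalars adopt the tensor
dtype so the graph is never silently promoted to float64); the loss
functions preserve float64 when given float64 inputs, which is what the
1e-9 oracle comparisons use.

## Loss and optimization

The segmentation loss is the sum of a focal term and a Dice term:

    L_FL   = -mean_i[(1 - p_i)^g y_i log p_i + p_i^g (1 - y_i) log(1 - p_i)]
    L_DICE = -(2 Σ y_i p_i) / (Σ y_i² + Σ p_i² + ε)

with g (gamma) = 2 by default, probabilities clipped to [1e-7, 1 - 1e-7]
before the logarithms, and ε = 1e-7 stabilizing the Dice denominator. The
focal sum is divided by the pixel count (mean reduction) so the loss scale
does not depend on batch or tile size; the optimum is unchanged. The Dice
term is kept in its negative form — its minimum is -1 at a perfect nonempty
match and 0 on disjoint supports — rather than the more common 1 - Dice;
the gradient differs only by a constant shift of the objective. The
combination weights default to (1, 1) and are configurable.

Optimization is Adam at an initial learning rate of 3e-4, divided by 10
after epochs 10 and 20; the full-scale recipe runs 30 epochs at batch 24,
the desk preset 15 epochs at batch 8. Data come through 5-fold
cross-validation splits (shuffled, seeded, disjoint, exhaustive).
Augmentation applies geometric transforms (random crop with resize-back,
horizontal/vertical flips, random scaling) identically to the phase tile
and its mask (nearest-neighbor for the mask, which therefore stays binary)
and photometric transforms (brightness, contrast, Gaussian noise) to the
phase tile only.

### Capacity-check protocol

The single-tile memorization check (Dice >= 0.95 within 200 steps) runs
with dropout and augmentation disabled and the learning rate at the recipe
value 3e-4. A memorization probe measures the architecture's capacity;
leaving a 0.5-dropout regularizer active would measure the regularizer
instead (with dropout on, the same check plateaus near Dice 0.6).

## Inference and seam smoothing

A full image is painted by tiling, batched eval-mode forward passes, mean
merging, and color filling. Residual discontinuities along tile division
lines are then treated by an aggregated-contextual-transformation (AOT)
style operator applied *only inside a seam mask* (pixels within half the
seam width, default 4 px, of any internal tile boundary). Each block routes
the image through parallel dilated 3x3 transformations (rates 1, 2, 4, 8),
merges the branches by averaging, and applies a gated residual update
(gate 0.5). The default operator uses fixed normalized kernels — it is a
deterministic smoother with no training dependency, preserving constants
exactly and never touching a pixel outside the seam mask. The dilation
rates and block count are configurable; a learned variant would slot into
the same interface but is deliberately not the default, so painting is a
pure function of one trained checkpoint.

## Evaluation metrics

Generated channels are scored against ground-truth fluorescence on the
0-255 scale with four per-image metrics:

* **Dice and Recall** over a tolerance-based pixel classification: a
  generated signal pixel is a true positive when the ground truth is also
  signal there *and* the intensities agree within 2 gray levels; otherwise
  it is a false positive, and unmatched truth-signal pixels are false
  negatives. Dice = 2TP/(2TP+FP+FN), Recall = TP/(TP+FN); undefined
  denominators return a flagged missing value rather than a number. A
  plain-overlap rule (intensity agreement ignored) is available as an
  option — the tolerance rule is strict by construction, since a probability
  of 0.99 already misses a saturated target by more than 2 levels.
* **SSIM** with the canonical Gaussian-weighted window: sigma 1.5 truncated
  at 3.5 sigma (an 11x11 kernel), K1 = 0.01, K2 = 0.03, population
  covariance, data range 255, averaged with the filter-radius border
  cropped. Backed by scikit-image; the test oracle re-derives the same
  definition with explicit pixel loops.
* **MSE** on intensities rescaled to [0, 1] (so 0.17 on an 8-bit image pair
  means root-mean-square error of about 105 gray levels).

Two methods' per-image score vectors are compared with the two-sided
Wilcoxon signed-rank test (exact null for n <= 25 pairs, normal
approximation beyond; all-tied inputs are flagged degenerate). The
signed-rank test is the correct member of the Wilcoxon family for paired
scores; the rank-sum test applies to independent samples.

## Synthetic organoid scenes

Every stage is testable without real data through a seeded scene generator.
It is a stylized statistical caricature, not an optical simulation: its job
is to encode exactly the structure the pipeline claims to exploit.

* **Geometry** — `n_crypts` (default 3) non-overlapping disks of radius
  28-40 px placed by rejection sampling in a 384x384 field (full-frame
  1536x1024 geometry is exercised by I/O tests; the smaller field keeps
  training desk-scale). The field outside the crypts is villus tissue.
* **Nuclei** — counts are Poisson at per-region densities (crypt 0.020,
  villus 0.003 nuclei/px²; the 6.7x contrast encodes the dense-nuclei
  signature of crypts), positions are dart-thrown with a hard-core minimum
  center separation of 4.5 px (1.5x the nucleus radius). The hard core
  makes nuclei behave like the solid objects they are: near-confluent
  packing in crypts without physically impossible overlaps, which is what
  makes density-based segmentation *and* per-cell counting simultaneously
  well-posed. At these intensities the rejection loss is negligible, so
  realized densities track the nominal ones.
* **Cell types** — crypt cells are stem with probability `lgr5_fraction`
  (default 0.4), Paneth with probability `ueai_crypt_fraction` (0.15), else
  enterocytes; villus cells are secretory with probability
  `ueai_villus_fraction` (0.08), else enterocytes. Stem cells exist only
  inside crypts, mirroring crypt-restricted LGR5 signal; UEA-I+ cells are
  Paneth in crypts and other secretory cells in villi.
* **Fluorescence rendering** — Gaussian spots (sigma = nucleus_radius/2
  = 1.5 px; UEA-I puncta use half that, giving the dot-like appearance)
  with per-cell amplitude jitter on a 0.05 background plus Gaussian noise,
  clipped to [0, 1].
* **Phase rendering** — each cell appears as a dark body with a brighter
  halo (a caricature of the phase-halo artifact), crypts carry extra
  fine-grained texture, and the field receives Poisson-count artifact blobs
  and additive Gaussian noise (sd 0.03).

All randomness flows through seeds derived from one master seed via NumPy
`SeedSequence` spawning, so datasets are byte-identical across runs. What
the generator does **not** model: real phase optics (point-spread,
shade-off, refractive-index variation), 3-D geometry, nucleus shape
variation, debris that correlates with tissue, or staining artifacts.
Passing tests therefore demonstrate that the pipeline machinery is correct
and that the mapping is learnable *when the phase image carries the
information*; they say nothing about accuracy on real microscope data.

## Phenotype quantification

The phenotypes mirror the standard readouts (crypt/villus area ratio,
marker-positive proportions) with an explicit, reproducible algorithm in
place of manual region tracing:

* **Crypt segmentation** — binarize the nuclei channel (Otsu by default),
  average in a moving window (default 25 px), threshold the density map,
  and clean up with morphological opening/closing (disk radius 3). The
  default threshold is data-driven in two steps: Otsu on the density map
  gives a provisional split, then the final cut is placed midway between
  the two class density plateaus (medians over the eroded core of each
  class). The midpoint rule is what makes the boundary unbiased: at the
  true region edge the moving window averages half crypt-level and half
  villus-level density, so thresholding at the plateau midpoint crosses
  exactly there. Plain Otsu sits systematically lower and inflates crypt
  area by roughly 10 % on this generator's geometry.
* **Cell counting** — binarize a channel, seed a watershed at local maxima
  of the Gaussian-smoothed intensity (smoothing sigma 1, minimum seed
  separation 3 px), split and label, and discard objects under 3 px. Seeds
  come from intensity maxima rather than distance-transform maxima because
  spot peaks survive when near-confluent nuclei merge into one connected
  component, while the distance transform of the merged blob does not
  resolve them. Two spots closer than the minimum separation still merge
  into one count — a documented resolution limit.
* **Marker assignment** — a nucleus is marker-positive when a marker-channel
  centroid lies within the match radius (default 3 px, the synthesis
  nucleus radius; must be set by the user for real data) of its centroid.
* **Reported fractions** — `lgr5_fraction` is the LGR5+ proportion of
  nuclei *inside the crypt mask*: LGR5 is biologically crypt-restricted, so
  the stem-cell fraction is a property of the crypt compartment, and both
  numerator and denominator are restricted to the same compartment (mixing
  an all-nuclei numerator with a crypt denominator, or vice versa, biases
  the fraction through boundary cells). `ueai_fraction` is the UEA-I+
  proportion of all cells, since secretory cells occur in both
  compartments.

On the default generator settings this recovers the geometric crypt/villus
area ratio with a mean absolute error of about 13 % (bound 20 %) and the
generating stem-cell fraction within about 0.02-0.09 absolute (bound 0.1),
with rank-perfect monotonicity across a 4-level stem-fraction sweep —
numbers the acceptance script recomputes on every run.

## Problem sizes and numerical choices

The shipped experiments are sized for a single CPU: 384x384 fields, 64x64
tiles, a 4-stage 16-channel model, 200 training tiles, 15 epochs (roughly
two to three minutes), and 10-scene phenotype panels. The full-scale
presets (1536x1024 frames, 256-px tiles, 5-stage encoder, batch 24, 30
epochs) are wired through the same code paths but are not exercised by the
test suite. Other numerical choices: probabilities clipped at 1e-7 before
logarithms; merge accumulators in float64; colorization rounds half away
from zero; ties in the scSE maximum route gradients to the channel branch;
the seam smoother clips its output to [0, 1]; checkpoint files embed the
architecture config as JSON inside a `.npz` archive so a model is
reconstructable from the file alone.

## Known limitations

* The synthetic phase texture is far easier than real phase contrast; the
  held-out Dice of ~0.78 on synthetic tiles is an upper bound of sorts, not
  a forecast for real data.
* The tolerance-based Dice/Recall rule is intentionally harsh on
  probabilistic outputs (see above); compare methods under the same rule
  rather than reading absolute values.
* Crypt segmentation assumes the whole field is tissue; empty (non-tissue)
  background would be counted as villus and would need an additional
  tissue mask.
* Counting saturates when spot spacing drops below the minimum seed
  separation; fractions are more robust than absolute counts because both
  numerator and denominator saturate together.
* The AOT seam smoother is a fixed operator by default; it reduces seam
  discontinuities but does not hallucinate structure across tiles.
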