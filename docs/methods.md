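# Methods

## Filter design

The bank starts from the 7th-order half-band Lagrange (maximally flat)
lowpass with taps {−1/16, 0, 9/16, 1, 9/16, 0, −1/16} and DC gain 2. All
prototype coefficients are stored as exact rationals (sixteenths) and only
converted to floating point when a kernel is materialised, so the unit tests
on taps and gains are bit-exact. Modulation by (−1)ⁿ produces the high-pass
{1/16, 0, −9/16, 1, −9/16, 0, 1/16}; convolution with {1, 2, 1} produces the
9-tap band-pass {1, 2, −8, −2, 14, −2, −8, 2, 1}/16 with |H(π/2)| = 2 and
exact nulls at ω = 0 and π. One numerical caveat documented by a test: the
true maximum of this low-order band-pass is 2.0798 at |ω| ≈ 1.73, slightly
past π/2 — the design anchors (gain 2 at π/2, nulls at the band edges) are
exact, but π/2 is not literally the argmax.

Rotation uses sparse digital-line placement rather than interpolation. For
θ ∈ {±26.56°, ±63.43°} (slopes 1/2 and 2) the ideal off-axis coordinate of a
tap is half-integer for odd tap indices; the tap is then split equally
between the two nearest lattice cells. This keeps the sums of coefficients
perpendicular to the filter direction exactly equal to the prototype taps
and preserves the zero coefficient sum, so no kernel responds to a constant
image. The default support is 9×9 because the band-pass prototype has 9
taps; a 7×7 mode built from the 7-tap high-pass (also zero-DC) is available
via `build_bank(support=7)` for a smaller first-layer kernel.

Bank application is direct 2-D convolution with symmetric (mirror) boundary
padding — zero padding would inject artificial edges at the borders that the
edge filters would amplify. A brute-force nested-loop convolution oracle in
the test suite pins the implementation to 1e−10.

## Network

Input is a single-channel 77×35 crop in [0, 1]. The first convolution
("Directional") is initialised with the eight directional kernels and
trained like any other layer; it uses symmetric padding so a constant input
yields exactly zero activation at initialisation. A depthwise 7×7 "Match"
convolution initialised as a centred identity follows (the initial forward
pass is therefore pure directional filtering), then a leaky ReLU
(slope 0.1). A parallel 1×1 convolution + batch norm taken from the raw
input is added to that path. Four stages of [2×2 ceil-mode max-pool →
skip-connection block] with 32/64/128/256 filters reduce 77×35 through
39×18, 20×9, 10×5 to 5×3, giving a flattened length of 5·3·256 = 3840;
Dense(64) → BN → ReLU → Dense(softmax) closes the network. Each
skip-connection block is 3×3 conv → BN → ReLU → dropout on the main path and
1×1 conv → BN on the shortcut, added elementwise. Ceil-mode pooling is the
only convention that produces the 77→39 and 35→18 ladder. The default
five-class model has 684,949 parameters (682,885 trainable; batch-norm
running statistics are counted separately), under the 715 k budget.

Ties at the softmax argmax resolve to the lower class index
(deterministic). The ablation `random_init=True` swaps only the directional
initialisation for He-normal noise; the match layer, architecture and seeds
are untouched, which isolates the value of the directional prior.

### Numerics and training

The layers are a compact numpy implementation (float32, NHWC) with
hand-coded backprop; convolutions run as one GEMM per layer over a
contiguous im2col buffer, and the depthwise kernel is numba-compiled
(a full-resolution depthwise convolution is memory-bound in pure numpy).
Central-difference gradient checks cover every layer. Training uses Adam
(lr 10⁻³, batch 32) on categorical cross-entropy, 60 epochs by default; the
training loop reseeds every stochastic component (shuffling, dropout) from
`TrainConfig.seed`, so runs with the same seed are bit-identical. Dropout is
0.2, batch-norm momentum 0.9, eps 10⁻⁵. These optimiser settings are package
defaults chosen for smooth convergence at the data scale of the synthetic
study; all are exposed in `TrainConfig`.

## Region-of-interest detector

A deliberately compact member of the aggregate-channel-features family:
eight grayscale channels (intensity, gradient magnitude, six hard-assigned
orientation bins) are 4×4 block-summed and smoothed with a [1,2,1]/4
triangle filter. The window size comes from the mean training box (in
4-px blocks); positive features are windows at the scale where the true box
matches the window (plus ±1-block jitter), negatives are random windows with
IoU < 0.3, and one round of hard-negative mining adds the detector's own
confident false positives. The ensemble is discrete AdaBoost over depth-2
scikit-learn trees with per-tree feature subsampling ('sqrt') and the
weighted error clipped to [0.02, 0.98]. The subsampling matters: on easily
separable data a single depth-2 tree is perfect, classical AdaBoost would
stop after one tree with an unbounded vote, and the window score saturates —
every bright region then ties at the maximum and localisation fails.
Detection scans a 2^(1/4)-step scale pyramid, scores all windows (trees are
evaluated vectorised over window positions), applies greedy non-maximum
suppression at IoU 0.5 and returns the best box, or `None` when nothing
clears the score threshold so the caller can fall back to manual crop
columns in the manifest. Training and detection are deterministic given the
config seed.

## Preprocessing and augmentation

Crops are resized by the single scale factor that fits them inside 77×35 and
padded symmetrically with the crop's median intensity — per-axis scaling
would distort the aspect-ratio cue that separates the later stages. The
augmentation set is exactly ten label-preserving variants per image: eight
integer translations (±3 and ±6 px along each axis) and two rotations (±5°),
median-filled. The displacement magnitudes are package choices (small
relative to the 35-px width); only the count and the operation types are
fixed by the protocol. Augmented images carry an `is_augmented` flag and a
derived `source_id`, and the evaluation layer refuses to score them, making
split-before-augmentation an assertable property rather than a convention.

## Evaluation protocol

Stage merging maps 1,2→1 and k→k−1 otherwise. Fold plans are stratified with
largest-remainder allocation and a remainder pointer that persists across
classes, so overall fold sizes differ by at most one (761 images give
validation folds of 153, 152, 152, 152, 152). Confusion matrices are
averaged elementwise across folds (fractional entries expected) and summary
metrics are recomputed from the averaged matrix. ROC curves are one-vs-rest
on the class probability with all observed thresholds (no interpolation);
AUC is the trapezoidal area; a seeded Monte-Carlo test pins a random-score
classifier to AUC 0.5 ± 0.05.

The significance procedure splits a test set into density-preserving subsets
(largest-remainder class quotas, 7 subsets of 30 by default), scores each
subset under both models, and reports means, n−1 standard deviations and a
one-sided p-value. The default test is Welch's two-sample t
(H₁: with-filters mean > without-filters mean); a direct normal-overlap mode
P(N(μ₀, σ₀) ≥ μ₁) is also provided because the procedure in the literature
fits normals to the two subset-accuracy histograms without naming a test.
The module computes and reports; it does not assert any particular
conclusion.

## Synthetic data

The generator emulates exactly what the pipeline needs from a cephalogram:
a 400×300 canvas with low-frequency background texture, a bright skull-like
distractor ellipse, and a stack of three vertebral bodies rendered as filled
polygons with carved parabolic notches, Gaussian blur (σ 1.1) and additive
Gaussian noise (σ 0.03). Stage-conditional geometry operationalises the
qualitative stage definitions: concavity depth < 0.05 of body height counts
as flat and U(0.15, 0.30) as notched, following the none/C2/C2+C3/all
pattern across stages; C3/C4 are trapezoids (taper U(0.72, 0.90), aspect
U(1.25, 1.65)) through stage 3, then near-rectangles with aspect
U(1.16, 1.45) (stage 4), U(0.90, 1.10) (stage 5) and U(0.62, 0.84)
(stage 6). All numeric shape parameters are the generator's own — the stage
scheme is qualitative — and neighbouring stages are kept adjacent in
parameter space so misclassifications concentrate between neighbours, as
they do clinically. Every sample's RNG stream is keyed by (seed, index), so
generation is reproducible and order-independent. An optional global tilt
parameter mimics posture inclination; it is off by default.

What the generator does **not** emulate: true radiographic projection
physics, soft-tissue shadows, inter-subject anatomical variability beyond
the parameter jitter, film artefacts, and the C1 vertebra / mandible
clutter. Passing tests therefore demonstrate that the pipeline's mechanics
are correct and that the network can learn the defined morphological cues —
not that clinical-data accuracy would reach any particular level.

## Problem sizes

The test suite exercises the pipeline at desk scale, chosen as the package's
own study conditions: stage recovery trains on 200 synthetic images per
merged class (5 classes, 30 epochs, fixed seed) and requires ≥ 0.80 held-out
accuracy; the detector trains on 42 images (64 trees, one mining round) and
requires ≥ 0.90 held-out recall at IoU 0.5; geometry rules are checked on
1000 draws per stage; the convolution oracle runs on images up to 32×32.

## Known limitations

* The exact per-angle coefficient grids of the original design are not
  reproduced; kernels are reconstructed from the defining equations and the
  sparse-rotation rule, and may differ in the outermost taps from any
  published table.
* The detector is a single-window, grayscale simplification of the ACF
  family — adequate as pipeline plumbing, not a detection benchmark.
* Training is CPU-only and single-threaded; the architecture is small
  enough that this is practical (tens of seconds per epoch on a thousand
  crops) but it is not a framework.
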