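# Methods

`leukosmear` implements a classical screening pipeline for acute
lymphoblastic leukemia (ALL) on stained peripheral-blood micrographs:
enhancement, lymphocyte-nucleus segmentation, hybrid texture/color feature
fusion, and binary classification, plus a desk-scale convolutional network
used as a feature extractor in a hybrid CNN–SVM variant.  This note records
the model choices, the parameters that matter, and the places where the
classical procedure is underspecified and the package had to commit to a
concrete rule.

## Image model and conventions

Images are real-valued arrays on the `[0, 255]` scale, 0-based, row-major,
origin top-left; quantization to 8-bit integers happens only on export.
Mid-pipeline values may be negative or fractional (the enhancement stage
subtracts a Laplacian response), so clipping is deferred to the points where
the contract requires it.

Color balancing (`normalize_channels`) is gray-world scaling: each channel is
multiplied by (mean of the channel means)/(channel mean).  The notion of
"channel area" this replaces is not well defined for an RGB image; per-channel
mean intensity is the standard reading, and the operation is exposed as a
switchable option (`RunConfig.color_normalize`).

## Enhancement

The enhanced image is `average_filter(x) − laplacian_filter(x)`, clipped to
`[0, 255]` only after the subtraction.  The average filter uses a 6×6 window
whose mean excludes the center pixel — 35 neighbors per pixel.  An even
window has no central cell; the package anchors the window covering pixel
`(r, c)` at rows `[r−2, r+3]` and columns `[c−2, c+3]`.  The Laplacian
defaults to the 4-connectivity kernel `[[0,1,0],[1,−4,1],[0,1,0]]`
(8-connectivity is a switch); borders are handled by edge-inclusive
reflection by default.  Filters run per channel; a luminance-only variant
would be an easy caller-side change since all operators accept single-channel
images.

A consequence worth knowing: the Laplacian amplifies independent pixel noise
by a factor of √20 (4-connectivity), so the enhanced image is *noisier* than
its input in flat regions while having much stronger edge response.  This is
why segmentation does not run on the enhanced image (below).

## Segmentation

### Adaptive region growing

Seeds sit on a regular 16-pixel grid.  All seed regions grow
*simultaneously*, one breadth-first wave per round; a pixel adjacent to a
region is admitted when

    |I(q) − running mean of the region| ≤ k · max(running std, 1),   k = 2.5.

Within a round, candidate pixels are processed in row-major order and a
pixel admissible to several regions goes to the lowest label.  Each pixel is
judged once per region, at the moment the wave reaches it.  Pixels no region
admits become new seeds (again grown competitively) until the partition is
exhaustive.

Two design points here were forced by instabilities of the naive reading:

* **Sequential growth with re-testing is unstable.**  If one region grows to
  exhaustion before its neighbors exist, every admission on an intensity ramp
  widens its running band, which admits the next ring of the ramp, without
  bound — a single region can engulf a nucleus plus its surroundings.
  Simultaneous competition removes the feedback loop: homogeneous interiors
  claim their territory before any band has inflated.

* **The union test cannot use the union's own spread.**  The post-growth
  merge pass fuses two adjacent regions when every pixel of the union lies
  within `k·max(s, 1)` of the union mean.  If `s` were the union's own
  standard deviation, a balanced union of two far-apart intensity modes would
  always pass (its spread is proportional to the separation), and all regions
  chain-merge for any `k ≥ 1`.  The band therefore uses the **pooled
  within-region** standard deviation, which measures internal noise rather
  than mode separation.

The emitted label map satisfies four conditions, asserted directly by
`verify_region_conditions`: the partition is exhaustive; every region is
8-connected; the homogeneity predicate `P` (all pixels within `k·max(std,1)`
of the region mean) holds within every region; and `P` with the pooled-std
band fails on every remaining adjacent pair.  Because Gaussian noise
guarantees a few >2.5 σ outliers in any large region, growth is followed by
an ejection-repair loop: pixels outside their region's final band are split
off as new connected regions and the check repeats.  The loop terminates —
violating regions strictly shrink, and singletons always satisfy `P` (std
floored at 1, deviation 0).  In practice this leaves a percent-level sprinkle
of one- or few-pixel regions in noisy areas; they are intentional (they are
exactly the pixels the band excludes) and are discarded later by the
ROI area gate and the morphological opening.

Region growing runs on the **luminance of the (color-normalized) input
image**, not the enhanced image: the enhancement stage trades flat-region
noise for edge contrast (above), and a stable noise floor is what makes the
adaptive band meaningful.  Nothing fixes which plane the growth must run on;
the choice is a config switch away (`region_grow` accepts any
single-channel image).

### ROI selection and morphological refinement

A region is nucleus-like when its mean color is saturated (`s ≥ 0.2`) and
blue-dominant (hue in `[200°, 320°]`) and its area is ≥ 64 pixels.  The ROI
is the union of qualifying regions; when nothing qualifies the mask is empty
and a warning is logged (a grayscale input always lands here — saturation 0).

Refinement applies closing (5×5 square structuring element), interior hole
filling, then opening.  A hole is a background component with no pixel on the
image border; border-connected background is never filled.  The border
convention pads dilation with background and erosion with foreground, so
masks touching the image border are not eaten from outside.  The composite is
idempotent.  Ordering rationale: closing first bridges the pixel-scale gaps
the band ejects, filling then removes enclosed holes, and opening last
removes debris smaller than the structuring element.

On the default generator (below), the chain
`select_roi ∘ morphological_refine` reaches a mean Dice overlap of ≈ 0.96
against ground-truth nucleus masks over 20 samples (the acceptance script
recomputes this).

## Handcrafted features (232 = 203 + 13 + 16)

All descriptors are restricted to the refined ROI of the **enhanced** image;
pixels outside the mask never contribute.

**LBP (203).**  The neighborhood is the full 5×5 window minus its center —
24 neighbors, enumerated ring by ring (outer ring first), clockwise from each
ring's top-left corner; bit `p` of the code is `s(g_p − g_c)` with
`s(c) = 1` iff `c ≥ 0`.  Codes live in `[0, 2²⁴)`; no standard LBP histogram
has 203 bins (uniform rotation-invariant coding gives 26 bins, full uniform
coding 555), so the fixed 203-entry dimensionality is realized by fixed-width
binning: `bin = floor(code · 203 / 2²⁴)`.  Only centers with a complete 5×5
window inside the image are coded; the histogram is normalized to sum 1 for a
nonempty ROI.  The descriptor is invariant to global additive intensity
shifts by construction.

**GLCM (13).**  Intensities are quantized to 16 equal-width gray levels.
One co-occurrence matrix per offset — (0,1), (−1,1), (−1,0), (−1,−1),
i.e. distance 1 axially and √2 diagonally — counts pairs with *both* pixels
inside the ROI, symmetrized and normalized.  The 13 canonical Haralick
statistics (angular second moment, contrast, correlation, sum-of-squares
variance, inverse difference moment, sum average, sum variance, sum entropy,
entropy, difference variance, difference entropy, and the two information
measures of correlation) are averaged across the four offsets, giving 13
values rather than 52.  Entropies use natural logarithms with `0·log 0 = 0`;
correlation-type statistics with zero denominators report 0.  The canonical set is the only defensible choice
of 13.

**FCH (16).**  RGB is quantized into 16 coarse bins (4×2×2 over R×G×B).
Crisp mode is the literal indicator rule — each pixel belongs wholly to the
bin containing it — and is the default, despite the method's "fuzzy" name,
because that is what the defining equation states.  A genuine fuzzy mode
assigns triangular membership split between the pixel's bin and the nearest
neighboring bin per channel (share scaled by `fuzzy_width`, memberships
multiplying across channels and summing to 1 per pixel).  Either way the
histogram of a nonempty ROI sums to 1.

Fusion is plain concatenation, LBP ‖ GLCM ‖ FCH, with stable per-entry names
(`lbp_000 … fch_15`) and layout offsets (0, 203, 216) exported as constants.

## Classifiers

Features are z-scored with training-partition statistics before any model
sees them; the fused vector mixes histogram masses (≈10⁻²) with unbounded
Haralick statistics (up to 10²), which no classifier should see raw.

**MLP.**  One hidden layer of 10 logistic units by default, softmax output.
The common description of this family of pattern nets — "10 hidden layers"
for a diagram showing 10 hidden *units* — is ambiguous; a 232-input stack of 10
sigmoid layers is untrainable with this setup, so 10 units is the default and
`TrainConfig.hidden_layers` accepts any stack for completeness.  Two presets
differ only in objective: `ann` minimizes the mean squared error between
one-hot targets and softmax outputs; `ffnn` minimizes cross-entropy.  Both
train by mini-batch gradient descent (batch 16, learning rate 0.5, up to 1000
epochs).  Early stopping: a failure counter increments on every epoch whose
validation loss does not improve on the best so far and resets on
improvement; training halts when the counter reaches 6, and the returned
model is the best-validation checkpoint, never the final epoch.  Full-batch
descent is available (`batch_size=0`) but is not the default: on the MSE
objective its early validation loss can drift upward for several epochs,
which the patience rule then mistakes for convergence.

**Max-margin (SVM).**  Linear soft-margin, `C = 1` (no kernel is stated
anywhere; linear is the conservative default).  The optimization is
scikit-learn's `SVC` behind this module's surface; the tests cross-check the
resulting margin against an exact small-case enumeration (the optimal
separating hyperplane of a separable toy is equidistant from two or three
defining points, so all candidates can be enumerated).

## Micro CNN

The layer operators — strided zero-padded cross-correlation, ReLU, max/avg
pooling, inverted dropout (eval is the identity), stabilized softmax — are
implemented directly from their defining equations and each is tested against
a brute-force loop oracle at 1e−9.  Convolution is cross-correlation (no
kernel flip), the modern convention; the flipped textbook form differs only
by a kernel reflection.  The default trainable network is
`conv(8,3×3) → relu → maxpool(2) → conv(16,3×3) → relu → maxpool(2) →
global avgpool → dense(32) → relu → dense(2) → softmax`, input 64×64
grayscale centered on the training mean, trained by mini-batch SGD with
momentum (lr 0.05, 100 epochs) on cross-entropy; deep features are the 32-unit
activation after the penultimate dense layer (`feature_tap`).

Two choices here were driven by measured failure modes.  Input resolution is
64×64 rather than a smaller grid because a normal nucleus of radius ~20 px on
the 512-px canvas shrinks to ~2.5 px at 64 — still resolvable — but would
vanish below ~1.3 px at 32.  And the head reads a channel-wise **global
average pooling** of the last feature map rather than the flattened map: the
nucleus lands at a random position, and with a dense layer over the 16×16
map the network memorizes training positions (perfect training accuracy,
chance test accuracy at desk-scale sample counts), whereas channel averaging
is position-invariant by construction — a dark-blob-detector channel averages
to the blob's area fraction, which is precisely the enlarged-nucleus cue.
The hybrid variant feeds the 32 tap features to the linear max-margin
classifier, replacing the softmax head.

## Evaluation

Accuracy, precision, sensitivity and specificity are the four standard ratio
formulas (×100, leukemia positive).  Ratios with zero denominators are
reported as NaN with a warning, never silently 0, because silent zeros
corrupt averaged reports.  AUC is the standard rank (Mann–Whitney) statistic
— the probability a random positive outscores a random negative, ties ½ —
reported as a percentage.  A "sensitivity divided by specificity" ratio is
sometimes mislabeled AUC; it is not a bounded area measure and cannot produce
a percentage scale, so only the standard rank statistic is implemented.  The error histogram uses 20 equal-width
bins over the observed error range; the regression diagnostic is the Pearson
correlation between targets and probability-like scores.

## Synthetic smear generator

The generator emulates ALL-IDB-style micrographs: a pale plasma background,
~40 red-cell discs (radius 18±3 px at the 512×512 default canvas, soft
2-px edges, central pallor), and one stained lymphocyte nucleus per image in
the blue-purple band, with additive Gaussian pixel noise (σ = 4).  Everything
is a pure function of `(params, seed)` — identical inputs give bit-identical
images.

The class signal is morphological, mirroring how blasts actually differ from
normal lymphocytes:

* **normal** — round, smooth nucleus (radius 20±2 px), fine chromatin
  (smoothed luminance mottle, amplitude 3);
* **leukemia** — enlarged nucleus (radius 33±4 px), irregular perturbed-
  polygon boundary (22% harmonic perturbation), a second overlapping lobe
  with probability 0.5, and coarse "lumpy" chromatin (amplitude 16, spatial
  scale 3 px).

Nucleus *color* is drawn from the same distribution for both classes, so the
color histogram alone cannot separate them; the discriminative information
lives in texture and boundary structure, which is what the LBP/GLCM channel
must capture.  The coarse-chromatin cue matters quantitatively: size and
irregularity alone act in opposite directions on every scale-normalized
descriptor (a larger nucleus has a *smaller* boundary-pixel fraction, a more
irregular one a larger one), and with chromatin texture included the fused
features become linearly separable on held-out data.

What the generator does **not** model: staining variability and illumination
gradients, touching/overlapping leukocytes, cytoplasm around the nucleus,
platelets, the L1/L2/L3 subtype taxonomy, and the full-field density of a
real smear.  Passing tests on this generator therefore demonstrate that the
pipeline machinery is correct and that the intended morphological signal is
recoverable end to end — not that the pipeline reaches any particular
accuracy on real micrographs.

## Pipeline, reproducibility and problem sizes

`run_pipeline` executes one of three variants — handcrafted features →
MLP/SVM; micro CNN end-to-end; micro CNN features → SVM — over a streamed
dataset (each image is loaded, reduced to its feature row, and released).
The stratified split takes `round_half_up(0.2·n)` of each class for testing
and then 20% of the remaining pool for validation, yielding the 31/8/10 and
38/9/12 partitions of the ALL-IDB1-style class sizes 49 and 59.  Class-balanced
augmentation (rotation at 90/180/270/±15/±30 degrees, flips, ≥80% crops
resized back, ≤10% reflect-padded shifts) applies to training records only
and is off by default in the handcrafted variant.  One global seed fans out
to per-stage seeds through a stable hash of the stage name, so stages can be
re-run in isolation; identical config and seed give byte-identical report
JSON.

Standard problem sizes: unit tests run the generator at a 160-px canvas; the
end-to-end checks and `scripts/acceptance.py` use the default 512-px canvas
with 200 images (100 per class), where the handcrafted and hybrid CNN–SVM
variants both reach ≈ 97% held-out accuracy (40 test images; the acceptance
script recomputes both).  These sizes exercise every stage at full fidelity
while keeping a complete run in the minutes range on one CPU.

## Known limitations

* The 203-bin LBP histogram realizes a fixed dimensionality that no standard
  LBP coding produces; its fixed-width binning is not rotation-invariant.
* The four-condition guarantee is exact but produces percent-level singleton
  regions in noisy areas by design; callers who want fewer regions should
  raise `similarity_k`.
* The MLP's MSE objective trains noticeably more slowly than cross-entropy
  and is more sensitive to the early-stopping transient (see above).
* The micro CNN is a desk-scale feature extractor, not a replacement for
  large pretrained backbones; its absolute accuracy is not comparable to
  transfer-learning systems.
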