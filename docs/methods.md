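# Methods

This note documents the models implemented in `ghcs`, the numerical
choices behind them, what the synthetic generators do and do not
emulate, and the known limitations. It states no empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## Stain normalization and augmentation

Color transfer follows the Reinhard recipe in the Ruderman lαβ
log-opponent space: RGB (scaled to [0, 1]) is projected onto LMS cone
responses, log10-transformed, and rotated onto the decorrelated
l (luminance), α (yellow–blue), β (red–green) axes. Each channel is
standardized with the source image's statistics and re-expressed with
the reference's, then mapped back. Numerical choices:

* **Epsilon 1e-6** is added before every log (so black pixels stay
  finite) and floors channel standard deviations (so a constant channel
  never produces an unbounded scale factor). Degenerate source channels
  are floored and logged, not errors.
* The LMS→RGB matrix is the **exact inverse** of the forward matrix;
  the conventional 4-decimal published inverse loses up to 2 intensity
  levels on a round trip, the exact inverse at most 1 (quantization).
* The transfer is idempotent up to quantization: renormalizing an
  already-normalized image to the same target moves no pixel by more
  than one level.

Augmentation is the fixed ten-member family
`[identity, 45°, 90°, 135°, 180°, 225°, 270°, 315°, hflip, vflip]`
(order fixed so output naming is deterministic). Multiples of 90° and
the flips are exact pixel permutations. The 45° family rotates about
the image center on the original canvas with bilinear interpolation and
reflection-padded corners — reflection rather than black fill so that
downstream tiles never contain out-of-distribution black wedges; this
requires square inputs, which the canonical 2048-px slides are. Only
the 45° and 135° warps are interpolated; 225° and 315° are exact 180°
grid rotations of those, which is mathematically identical to direct
warping because the 180° rotation is a grid isometry that commutes with
bilinear sampling.

Tiling is a row-major grid of disjoint `tile_size` squares anchored at
the top-left; remainder strips at the right/bottom are dropped (the
2048/256 case divides evenly; for other sizes choose a divisor tile
size if full coverage matters). Tiling followed by reassembly is
bit-exact for divisible dimensions.

## Candidate region and the 10 descriptors

The candidate (dark-tissue) region is Otsu thresholding on the
grayscale complement — hematoxylin-dense tissue is darker than the
eosin background — followed by morphological closing (radius-2 disk)
and removal of components under 20 px. A featureless tile falls back to
the whole-tile mask with a logged warning so the descriptor vector is
always defined.

Descriptor definitions (fixed order, all finite):

| feature | definition | scale |
|---|---|---|
| mean_value | mean HSV value over the tile | [0, 1] |
| mean_saturation | mean HSV saturation over the tile | [0, 1] |
| compactness | p²/(4πA) of the candidate region | ≥ ~1 |
| mean_intensity | mean green channel over the region | [0, 1] |
| area | region pixel count | px |
| mean_hue | circular mean of HSV hue over the region | [0, 1) |
| total_energy | region pixel count / Σ region green intensity | — |
| total_entropy | Shannon entropy of the 256-bin gray histogram | bits |
| mean_gradient_amplitude | mean Sobel magnitude over the region | — |
| third_moment | sample skewness of region gray intensities | — |

Hue is averaged **on the unit circle** (atan2 of mean sine/cosine) —
an arithmetic mean of hue angles is wrong for the red wrap-around that
H&E pinks straddle. Skewness is defined as 0 when the region is
constant (σ = 0). The energy denominator is epsilon-guarded with a
warning.

**Perimeter estimator.** Compactness is sensitive to how the perimeter
of a rasterized region is measured, so the estimator is part of the
contract: the outer boundary of each 8-connected component is traced
(Moore neighbourhood, Jacob's stopping criterion) and the Freeman chain
is summed with the Vossepoel–Smeulders calibrated step weights, 0.980
per axial and 1.406 per diagonal step. The naive 1/√2 weighting
overestimates smooth digital boundaries by about 5%, which alone pushes
a disk's compactness to ≈1.10; with the calibrated weights a radius-50
digital disk measures ≈1.07. Isolated pixels count 4.0 (unit-square
convention); components this small are normally removed before
measurement.

All ten descriptors are statistics of intensities or region geometry,
so they are invariant (to 1e-9, i.e. summation-order noise) under the
90°-family rotations and flips of the (image, mask) pair — asserted as
a property test.

**Standardization.** Features are z-scored with training-set mean/std
before mixture fitting and the parameters stored in the model file:
mixtures over raw heterogeneous scales (area in thousands of px next to
hue in [0,1)) are numerically fragile and make the covariance ridge
meaningless.

## The mixture-density Bayes classifier

Per class, an s-component full-covariance Gaussian mixture is fitted by
EM. Choices that matter:

* **Initialization**: means seeded k-means++-style from the data
  (seeded RNG), covariances at the pooled sample covariance, weights
  uniform; `n_init` (default 5) restarts keep the best final
  likelihood.
* **Regularization**: `reg_covar` (default 1e-6) is added to covariance
  diagonals at every M-step; the fitted Σ therefore equals the biased
  sample covariance plus the ridge exactly in the s = 1 case.
* **Convergence**: relative log-likelihood change below `tol`
  (default 1e-6) or `max_iter` (200). The observed-data log-likelihood
  trace is checked for monotonicity on every fit (a structural EM
  property; violations beyond 1e-8 relative are logged).
* **Collapse handling**: a component whose responsibility mass
  vanishes (< 1e-8·n) is re-seeded from a random datum with the pooled
  covariance, and logged.
* **Numerics**: all densities flow through log-space
  (Cholesky log-pdf, log-sum-exp); the posterior is a sigmoid of the
  log-odds, so far-tail points never underflow and exact density ties
  give exactly 0.5.

**Component-count selection** is by mean held-out log-likelihood over
`n_val_splits` (default 5) random splits with `val_fraction` 0.3 —
chosen over validation *accuracy* because likelihood is defined per
class independently of the other class's model. The smallest s within
`selection_margin` (default 5e-3 nats/sample) of the best mean score is
selected — the analogue of the one-standard-error rule. Without the
margin, a redundant extra component wins on genuinely unimodal data for
a noticeable fraction of seeds by a few millinats of sampling noise;
the margin was calibrated across seeds on unimodal and well-separated
trimodal data, where the score gaps of real structure are orders of
magnitude larger. When the data are too small for held-out scoring at
any grid value, the smallest feasible s is used with a warning.

The decision threshold τ is exposed (default 0.5 = MAP). Screening
use lowers it — e.g. τ = 0.2 flags any tile with ≥20% posterior
probability of abnormality — and lowering τ can only increase
abnormal-class recall (asserted as a monotonicity test).

The model file is schema-versioned JSON carrying standardization, τ,
priors and per-component weight/mean/covariance; the round trip is
lossless (save→load→save is byte-identical).

## IFCM segmentation

The segmenter minimizes the fuzzy objective Σ u_xy^z (D_xy + G_xy) with
D the squared feature distance to the prototype and G the trade-off
weighted fuzzy factor over the (2r+1)² window (default 3×3),

    G_xy = Σ_{j∈N(x), j≠x} 1/(d_xj + 1) · (1 − u_yj)^z · ‖e_j − f_y‖².

The update equations are the standard Lagrangian closed forms for this
objective family (the FLICM family):

    u_xy ∝ (D_xy + G_xy)^(−1/(z−1)),  rows normalized;
    f_y = Σ u_xy^z e_x / Σ u_xy^z.

Design and numerical choices:

* **Variants.** `flicm` (default) includes the neighbour's data term
  ‖e_j − f_y‖² in G; `paper_literal` drops it, leaving a pure
  membership-smoothing penalty — without a data term the factor cannot
  steer memberships toward locally coherent *clusters*, only toward
  agreement, which is why it is not the default; `none` disables G
  entirely and is exactly standard FCM (verified against an
  independent implementation to 1e-6 in prototypes).
* **Jacobi sweeps.** G is computed from the previous iteration's full
  membership matrix, never in-place, so results are independent of
  pixel ordering and bit-reproducible under a fixed seed.
* **Borders** use truncated neighbourhoods (no padding, no weight
  renormalization) — border pixels simply have fewer neighbours.
* **Initialization** is seeded uniform-random row-normalized
  memberships; termination when the maximum prototype drift falls
  below `epsilon` (default 1e-4) or `max_iter` (100), with an explicit
  `converged` flag otherwise.
* **Zero-cost pixels** (coincident with a prototype at zero factor)
  get crisp membership by the limit convention; a pixel at zero cost
  for every cluster gets a uniform row with a warning.
* **Convergence guarantees.** For the factor-free variant the FCM
  objective is non-increasing across sweeps (asserted). For the
  coupled flicm objective no such monotonicity holds in general; only
  prototype-drift convergence is asserted. A related consequence: on a
  noise-free two-level image the factor-free fixed point puts
  prototypes exactly at the levels, while the flicm fixed point is
  offset by O(boundary/area) (≈3e-3 on a 64-px disk) because boundary
  pixels retain mixed memberships; labels are unaffected.
* **Feature space** defaults to the per-pixel lαβ triplet of the
  (ideally stain-normalized) image; grayscale mode is available and is
  what the phantoms use. Images beyond 512 px on a side are segmented
  per 256-px tile and stitched, with each tile's clusters put in
  canonical order (ascending first-feature prototype) so labels remain
  comparable.
* **Abnormal-cluster policy**: lowest mean prototype value by default
  (hematoxylin-dense nuclei are dark); `highest-luminance` and
  `by-index` alternatives exist because the mapping from cluster to
  tissue class is a modeling decision, not an algorithmic one.

## Evaluation

Overall metrics use the standard confusion-matrix definitions with
abnormal as the positive class. The per-class report *additionally*
reproduces the column-wise convention used in published gastric
histology confusion-matrix breakdowns (normal recall = TN/(TN+FN),
normal specificity = TP/(TP+FP), normal precision = TN/(TN+FP), the
abnormal row mirrored), so printed tables can be checked digit for
digit. Display values are percentages rounded **half-up** at two
decimals with full precision kept alongside; a few published values are
truncations rather than roundings (e.g. 98.476 printed as 98.47) and
differ from this display in the last digit. Metrics with zero
denominators are reported as an explicit `undefined` marker, never as
0. Dice and Jaccard satisfy DC = 2·JI/(1+JI) identically; the
empty-vs-empty pair is defined as perfect agreement (1.0). Pixel
outcome maps color TP green, FP blue, FN red, alpha-blended over an
optional background; the posterior heatmap upsamples tile posteriors by
replication through a monotone blue→red map (R = 255p, B = 255(1−p)),
serving as the interpretability surrogate for saliency overlays.

## Synthetic data: what it does and does not show

`make_tile` renders an eosin-pink Gaussian-textured background with
anti-aliased elliptical hematoxylin-colored nuclei. Defaults: 256-px
tiles; 40 expected nuclei/tile for normal, 90 for abnormal (Poisson);
radii 3–6 px (normal) vs 4–10 px (abnormal); eccentricity 1–1.4 vs
1–2.5 (pleomorphism); abnormal tiles contain one contiguous elliptical
lesion (25–40% of the tile's side) inside which placement density is
doubled, and its footprint is the ground-truth mask. The defaults were
chosen once so that the class contrast on nucleus count alone exceeds
Cohen's d = 1 — enough for the descriptor pipeline to be meaningfully
testable, not so much that every test is trivial.

`make_feature_dataset` draws from known per-class mixtures in the 10-D
descriptor space: two equal components per class split ±2.5 on one
axis, classes offset by 5 component-σ on another, identity covariance.
The resulting Bayes error (Monte-Carlo integrated, equal priors) is
well under 2%, so the ≥95% held-out accuracy requirement is attainable
by construction, while the within-class bimodality still exercises
multi-component EM. `make_phantom` produces piecewise-constant stripe,
disk or checkerboard layouts with exact label maps; noise (Gaussian,
then salt-and-pepper at the extreme levels) is applied after ground
truth is captured.

What passing tests on this material does **not** show: real H&E tiles
have textured stroma, glandular architecture, overlapping nuclei with
chromatin structure, and staining gradients none of which are emulated;
the lesion boundary here is a clean ellipse; and the feature mixtures
are exactly Gaussian, which real descriptor distributions are not. The
synthetic results validate the *implementation* (formulas, updates,
bookkeeping, determinism) and the method's behaviour under controlled
contrasts — not clinical performance, which requires the public
datasets the toolkit can ingest but does not ship.

## Problem sizes and determinism

The acceptance script runs the full-scale augmentation bookkeeping (84
slides at 2048², ten transforms, 64 crops each); the statistical
checks use 4,000 points for mixture recovery, 3,000/900 for component
selection, 1,000/class for the classifier, 96-px phantoms for the
segmenter, and an 80-tile end-to-end pipeline run — sizes chosen so the
whole script completes in a couple of minutes on one CPU while keeping
every standard error far from the asserted bounds. Every stochastic
stage takes an explicit seed; the end-to-end pipeline is byte-
reproducible under a fixed seed (asserted on `report.json`).

## Known limitations

* Two classes only; the Bayes rule and report layouts assume
  normal/abnormal.
* The candidate-region extractor is a fixed Otsu-based heuristic; on
  tiles whose tissue is lighter than the background it selects the
  complement of the intended region.
* The per-tile stitching path for large images fits prototypes
  independently per tile; a slowly varying stain gradient can flip the
  canonical cluster order between tiles.
* `paper_literal` mode is provided for completeness but is expected to
  under-segment (its factor ignores feature distances).
* Runtime is O(pixels · clusters · window) per IFCM sweep in vectorized
  numpy; no GPU or multi-core path.
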