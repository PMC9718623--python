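# Methods

`grainsight` implements a two-stage pipeline for identifying rice-grain
varieties from single-kernel photographs: (1) saliency-based segmentation
isolates the grain from the stage background; (2) deep features from two
backbone views are fused by a maximum-correlation rule, pruned by an
improved butterfly optimization algorithm (BOA) hybridized with the
cross-entropy (CE) method, and scored by a panel of standard classifiers.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Saliency segmentation

The image is over-segmented into SLIC superpixels (default `n_segments =
200`) summarized by CIELAB means and normalized centroids. Nodes form a
graph whose affinity is `w_ij = exp(-||lab_i - lab_j|| / sigma_c)` on a
connectivity pattern of adjacent nodes, neighbors-of-neighbors, and all
border-border pairs — the usual closure for boundary-seeded ranking.
`sigma_c = 10` Lab units: small enough that a bright grain (ΔL ≈ 50–60
against a dark stage) is effectively decoupled from the background
community, large enough that background texture noise (ΔL ≈ 3–5) is not.

**Manifold ranking.** Scores solve `(I − α P) r = y` with `P = D^{-1} W`
the random-walk normalization and `α = 0.99`. We deliberately use the
row-stochastic conjugate of the symmetric-normalized resolvent
`(I − α D^{-1/2} W D^{-1/2})^{-1}` (they differ by the similarity
`D^{1/2}`): at `α` close to 1 the resolvent is dominated by its Perron
term, which for the symmetric form is proportional to `sqrt(degree)` —
on graphs whose salient region is small and weakly coupled this degree
bias swamps the seed signal entirely. For the row-stochastic form the
Perron term is a constant vector, which the min-max normalization
applied to every stage output cancels exactly, so the seed-dependent
structure survives. `α = 0` returns the seeds unchanged, and the
resolvent's nonnegativity gives the monotone-seed property checked in
the tests.

**Stages.** Background saliency ranks three times with the top, left and
right border nodes as seeds (the bottom border is not used as a seed),
multiplies the three rankings, min-max normalizes, and complements.
Compactness saliency combines the diffusion-weighted spatial variance of
each node's support (`I_v`) with the distance to the
background-saliency-weighted image center (`I_d`); the two cues are each
min-max normalized before summation because their raw scales differ by
about 5× (variance is in squared position units) and the distance term
otherwise dominates. The combined map `I_1 = norm(I_b + I_f)` re-weights
the graph with a saliency-similarity kernel
`exp(-|I_1(i) − I_1(j)| / sigma_s)` (`sigma_s = 0.1`, exponent `Z = 1`,
both exposed) added on the first-stage sparsity pattern, and a second
ranking pass seeded with `I_1` yields the refined map `I_2`.

**Thresholding.** The per-pixel raster is binarized at
`min(2 · mean, 0.95)` — the standard adaptive rule for saliency maps.
Otsu's threshold is available (`method="otsu"`) but is not the default:
when the object covers only a few percent of the frame, Otsu's
between-class criterion splits the broad background mode even when node
saliency separates the object perfectly (we measured grain saliency 0.98
vs. background maximum 0.5 with Otsu landing at 0.26). A constant
saliency raster yields an all-background mask with a warning. Masked
images are Lab-transformed with the background zeroed for downstream
feature extraction.

## Backbone specifications and the mock extractor

DarkNet19 (19 convolutions, 5 max-pools, 1×1 head convolution with one
filter per class, global softmax) and SqueezeNet (7×7 conv, 8 fire
modules with max-pools after fire4-group and fire8, 1×1 head conv,
global average pool) are encoded layer-by-layer, and `infer_shapes`
reproduces their reference output tables arithmetically: 3×3
convolutions pad 1, 1×1 pad 0, pools pad 0, `out = floor((in + 2p − k)/s)
+ 1`. The nominal input is 224×224; SqueezeNet's printed 111×111 conv1
output is arithmetically consistent with a 227 input, which
`infer_shapes(spec, input_hw=227)` verifies. The feature tap is the layer
feeding the head, globally average-pooled: 1024 features for DarkNet19,
512 for SqueezeNet (configurable).

Real pretrained weights require a deep-learning runtime and are outside
this package's scope; `load_real_backbone` raises with that message. All
executable feature extraction uses `MockFeatureExtractor`: a fixed-seed
random projection of the **sorted** 32×32 grayscale downsample. Sorting
makes the representation an intensity order-statistic — invariant to
where the grain sits in the frame, as pooled convolutional features
approximately are, while preserving object area and texture
distribution, which carry the class signal. Head replacement
(`swap_head_and_finetune`) fits a ridge least-squares readout on the
tapped features ("train head only"); zero epochs is a strict no-op, and
the tap contract is unchanged by training.

## Maximum-correlation fusion

Two feature views are concatenated (first view's columns first) and
pruned by two rules. R1 (redundancy): scanning columns in order, a
column is dropped when its |correlation| with a still-kept earlier
column reaches `tau_high = 0.90`. R2 (corroboration): a survivor is
dropped when its maximum |correlation| against **all original columns of
the other view** is at most `tau_low = 0.05` — a feature the second view
does not echo at all is treated as view-specific noise. Constant columns
have correlation 0 by definition and fall to R2. Both rules are
deterministic given the inputs; earlier columns win ties.

The default measure is absolute Pearson correlation. A binned maximal
correlation (the supremum of `corr(g(X), h(Y))` over Borel transforms)
is provided for nonlinear association: both margins are discretized into
near-equal quantile bins, and the estimate is the second singular value
of the standardized contingency matrix — the closed form of the
alternating-conditional-expectations fixed point for discrete variables.
Two corrections stabilize it: (i) under independence the raw second
singular value concentrates at the Marchenko–Pastur edge
`e = 2 sqrt(n_bins − 1)/sqrt(n)`, so the estimate inverts the noise
model `sv² ≈ cv² + e²(1 − cv²)`; (ii) because maximal correlation
provably dominates |Pearson| (the identity transform is admissible), the
returned value is floored at the linear estimate, which binning
attenuation would otherwise undercut.

## Improved butterfly optimization

Butterflies are positions in `[0,1]^D` over the fused columns. Fragrance
follows the canonical power law `f = c · I^a` with sensory modality
`c = 0.01` and exponent `a = 0.1`; the stimulus intensity is the inverse
fitness `I = 1/(fitness + 1e-6)`, so better solutions take bolder steps
in a minimization setting. With probability `switch_p = 0.8` a butterfly
moves globally, `P += (rn² · b_p − P) · f`, toward the best-known
position; otherwise locally along a random peer difference,
`P += (rn² · P_k − P_l) · f`; positions clamp to the unit box. Positions
binarize at 0.5; an all-zero mask is repaired to the single
largest-position bit.

The CE hybrid maintains a Bernoulli distribution `a_k` over feature
subsets. Each iteration the elite fraction (`rho = 0.1` quantile by
fitness) refits `a⁺` as the per-dimension elite bit mean — the
KL-minimizing Bernoulli fit — smoothed as
`a_{k+1} = α_s a⁺ + (1 − α_s) a_k` with `α_s = 0.7` and clipped to
`[0.01, 0.99]` so sampling never degenerates. In the default `inject`
mode, `n_ce` fresh samples from `Bernoulli(a_k)` replace the worst
butterflies each iteration (`n_ce` defaults to the population size); in
`replace-global` mode CE sampling substitutes for the global move.
Best-ever bookkeeping makes the fitness trace non-increasing, and with
CE disabled the loop is canonical BOA. Defaults: population 30, 200
iterations.

**Wrapper fitness.** `fitness = cv_error(5-NN) + λ · n_selected / D`
with `λ = 0.01`. The error is averaged over **two independent stratified
3-fold partitions** (12 classifier fits per evaluation) rather than a
single fixed partition: a selection run evaluates on the order of 10⁴
subsets, easily exploiting the ~1.5% standard deviation of a single
partition's error estimate, and the second partition halves the variance
available to such overfitting. Evaluations are memoized by mask, since
subsets recur heavily once the search concentrates.

## Classifier panel and metrics

Eleven named classifiers behind a standardizing pipeline: linear,
quadratic and cubic SVMs (one-vs-one, `C = 1`; polynomial kernels use
`coef0 = 1`, the inhomogeneous `(1 + ⟨x,y⟩)^d` form of the usual
"quadratic/cubic SVM" presets), distance-weighted and cosine 10-NN,
linear discriminant analysis, and five ReLU multilayer perceptrons named
by the MATLAB Classification Learner convention (narrow = 10,
medium = 25, wide = 100 hidden units; bilayer = 10×10;
trilayer = 10×10×10; 1000 max epochs). The default protocol is a
stratified seeded 50:50 holdout; 10-fold cross-validated prediction is
available via `use_cv`. The cubic SVM joins only the post-selection
panel (`FULL_PANEL`), matching the benchmark's reporting.

Metrics are macro-averaged percentages — appropriate for class-balanced
data — so FNR ≡ 100 − macro recall and F1 is the harmonic mean of macro
recall and macro precision. These identities are enforced in code and
audited against the bundled published tables: recomputing F1/FNR from
each printed recall/precision pair reproduces the printed cells to one
unit in the last printed digit, except for cells recorded in
`reference_tables.ERRATA` (one truncated F1 and one garbled recall in
the published tables, documented there). Classes absent from a test
split are excluded from macro averages with a warning. Wall time is
reported but never asserted.

## Synthetic data

**Images.** Each sample is one bright convex grain — a rotated ellipse
with sinusoidal luminance texture along its major axis — on a dark
Gaussian-noise background, with a mild warm tint. Classes differ in
semi-major axis (0.20–0.32 of the frame length, growing with class id),
aspect ratio (0.30–0.54) and texture frequency (2–8 cycles per grain),
ranges disjoint enough that area and aspect alone separate classes. The
grain spans 40–65% of the frame length, matching single-kernel macro
shots where the kernel occupies roughly half the frame; boundary-prior
saliency presumes the object is not a vanishing fraction of the image.
Not modeled: touching or overlapping grains, specular highlights,
shadows, photorealistic texture. Passing segmentation tests therefore
demonstrate correct behavior of the graph-ranking machinery under its
stated assumptions, not robustness to real-world imaging artifacts.

**Feature matrices.** `k_informative` columns are class-conditional
Gaussians (s.d. `sigma = 1`); column `j` is the dominant discriminator
of one class pair (pairs cycled in order) with class means
`±0.675 · delta` for that pair and 0 for the rest. This makes every
informative column individually load-bearing — dropping it collapses one
pair's margin — while the full block separates all classes comfortably
(`delta = 3σ` gives ≥ 95% informative-only 5-NN accuracy). Redundant
columns copy an informative source plus Gaussian noise solved
analytically so the sample correlation is ≈ `rho` (default 0.7 — strong
enough to be redundant, noisy enough that a copy cannot silently
substitute for its source in the wrapper). Noise columns are
label-independent with s.d. `sigma_noise = 3`, deliberately larger than
the informative noise: raw network activations have heterogeneous
scales, and on unstandardized k-NN distances such channels are actively
harmful, which is what makes their exclusion a learnable signal rather
than a coin flip. `delta = 0` removes all class signal (wrapper accuracy
falls to chance).

## Pipeline and problem sizes

`run_all` executes synth → segment → extract (two mock views) → fuse →
select → classify, writing every intermediate table as CSV plus a JSON
manifest of per-stage dimensions; one global seed fans out to per-stage
seeds through a fixed `SeedSequence` rule, so two runs with the same
config produce identical artifacts apart from timestamps. Desk-scale
defaults — 5 classes × 40 images at 128 px, 128-dim mock extractors,
population 30 with 40 selection iterations, the full 11-member panel —
complete in well under a minute on one CPU while exercising every stage;
the selector's own default remains 200 iterations. The two mock views
are projections of the same underlying statistic, so fusion prunes them
hard (52 of 256 columns kept in the seed-1 run) — an extreme but valid
regime for the redundancy rule; real backbone pairs would retain more.

## Known limitations

- The mock extractor is linear in the sorted downsample: it inherits the
  fixture's separability but cannot emulate the representational power
  or failure modes of trained convolutional features.
- The boundary-prior segmentation assumes a single bright object away
  from three of the four borders; multiple grains, border-touching
  grains, or dark-on-light stages violate its assumptions.
- The binned maximal-correlation estimate is consistent only up to
  binning resolution; with `n_bins = 8` associations expressed purely
  within bins are invisible.
- Recovery rates of the selector are specific to the planted design and
  the wrapper classifier; they are not guarantees for arbitrary
  correlated feature sets.
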