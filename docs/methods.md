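# Methods

This note documents the models and procedures implemented in `moma`, the
assumptions behind them, the defaults that matter, and what the synthetic
data used by the tests does and does not establish.

## Pipeline overview

A whole-slide (or large-field) RGB image is tiled into a non-overlapping
grid of square patches (default 1000×1000 px; all synthetic studies in this
repository use 64 px tiles so the full pipeline runs on one CPU in minutes —
the tile size is a plain configuration value and nothing downstream depends
on it). Tiles that are mostly unsaturated are flagged as background (HSV
saturation < 0.05 on ≥ 75 % of pixels) and excluded. Tissue tiles are
stain-normalized (below), embedded by a frozen convolutional backbone into
fixed-length vectors, and each slide's vectors form a *bag* in the
multiple-instance-learning sense: the slide carries one label, its tiles
none.

## Optical density and Macenko stain normalization

Stains mix linearly in optical density, not in intensity. We use
`OD = −log10((I + 1)/(I0 + 1))` per channel with illuminant `I0 = 255`; the
+1 offset keeps zero-valued pixels finite, and the transform is an
order-reversing bijection on [0, 255].

Stain estimation follows Macenko: drop transparent pixels (any channel's OD
below `od_beta = 0.15`), take the top-2 right-singular plane of the OD
cloud, compute each pixel's angle in that plane, and back-project the angles
at the 1st and 99th percentiles (`alpha_percentile = 1`) as the two extreme
stain directions; they are sign-corrected to be nonnegative and normalized
to unit length. Column order is fixed by the convention that hematoxylin
carries the larger blue-channel OD component. Per-stain robust maximum
concentrations are the 99th percentile of nonnegative deconvolution
(least squares with negative parts clipped — equivalent to per-pixel NNLS
for well-separated bases and far faster). Normalizing a tile means:
deconvolve with the source basis, rescale concentrations by
`reference_max / source_max`, recompose with the reference basis, invert
the OD transform.

Degenerate inputs: fewer than two usable pixels, or an OD cloud whose
second singular value is below 1 % of the first (a one-stain image), raise
an "insufficient stain signal" error. The 1 % floor was set from the
forward model: 8-bit quantization alone gives single-stain renderings a
second-singular-value ratio of ≈ 0.35 %, while genuine two-stain clouds sit
orders of magnitude higher.

The synthetic stain-calibration pattern (`make_stain_gradient_concentrations`)
sweeps from pure hematoxylin to pure eosin with 20 % pure plateaus at both
ends and maximum concentration 2.4. The plateaus put the robust percentile
angles well inside the pure-stain pixel sets, and the 2.4 ceiling matters:
eosin's red-channel OD component is 0.07, so a pure-eosin pixel only
survives the any-channel 0.15 transparency filter when its concentration
exceeds ≈ 2.1. With this pattern the planted stain matrix is recovered with
cosine ≥ 0.999 noiselessly and ≥ 0.99 at OD noise 0.02.

## Feature extraction

The backbone is an interface: any callable from a tile batch to fixed-length
vectors. The shipped backbones are deterministic random-feature
convolutional extractors — fixed-seed random filters, ReLU, and per-filter
mean/max pooling over a spatial grid ("random kitchen sink" embeddings,
frozen by construction). `tiny` (8 filters, 16-dim) drives all synthetic
studies; `default` (64 filters, 4×4 pooling grid) emits 2048 features per
tile, the dimensionality contract of a production residual-network
embedding, for which it is a drop-in slot. No training occurs at this
stage; permuting tiles permutes feature rows identically.

## Microenvironment clustering

Tile features from the *training* slides are clustered with k-means
(k-means++ init, Lloyd iterations, 10 restarts, fixed seed) into K = 10
clusters, a count motivated by the ~10 recurring colorectal tissue-region
types (tumor, stroma, lymphocytes, debris, mucus, muscle, adipose,
background, normal, other). Cluster identities are positional — no semantic
matching to named types is implied. The model is fit globally (not per
slide) so cluster identity is consistent across slides; the per-cluster
transformer streams and the instance loss need this. Assignment is
nearest-centroid with ties to the lower index; a slide may leave some
clusters empty, which downstream code treats as absent streams.

## The slide-level model

Per slide: (1) tile features are z-scored with statistics frozen on the
training bags (raw backbone activations have heterogeneous scales and the
un-standardized problem is badly conditioned), (2) a shared affine map
reduces them to `reduced_dim` (512 default, 16 in the tiny config), (3)
each nonempty cluster's tiles form an unordered token set encoded by a
pre-norm transformer (512 hidden, 8 heads, 2048 MLP, dropout 0.1, depth 2
default; positional encodings are deliberately omitted — bags are sets),
(4) gated attention (`w^T(tanh(Vh) ⊙ σ(Uh))`, softmax over tokens) pools
each cluster's tokens to a cluster vector, and a second gated attention
pools cluster vectors to the slide embedding. The two-level pooling
reconciles per-cluster encoding with a single slide representation; both
attention levels are exposed and their product is a per-tile attention that
sums to one over the slide. (5) An affine head + softmax yields class
probabilities; applied per post-transformer token it yields the instance
scores used by the instance loss. A `simple` (ungated tanh) attention
variant is available by configuration.

The full forward pass is permutation-invariant at the slide level,
deterministic in eval mode, and duplicating every tile of a cluster leaves
its pooled vector unchanged (attention pooling is a weighted mean).

## Losses

*Bag loss*: weighted cross-entropy `−w_y log p_y` with inverted class
weights `w_c = N/(C·n_c)` computed from per-class tile counts, so
minority-class gradients are not swamped. Probabilities are clamped at
1e-12 with a warning.

*Instance loss*: the clusters are ranked by attention; the top 3 get a
positive pseudo-label, the bottom 3 a negative one (counts reduced
symmetrically when fewer than six clusters are nonempty; top ties break to
the lower cluster index, bottom ties to the higher). Every tile inherits
its cluster's pseudo-label. The per-tile penalty is the smoothed hinge
`ℓ_τ(z) = τ·log(1 + exp((1−z)/τ))` on the margin
`z = ±(s_target − s_strongest_other)` — the binary smooth-SVM form, applied
one-vs-rest for multiclass heads. `ℓ_τ` upper-bounds the hinge and
converges to it pointwise as τ → 0⁺, with gap τ·ln 2 at z = 1. τ defaults
to 1.0 and is a per-task tunable.

*Total loss* is the unweighted sum of the two terms. Optimization follows
the production recipe: SGD, lr 1e-3, momentum 0.9, weight decay 5e-4, batch
size 1 (one slide per step), cosine annealing, with the epoch budget scaled
to the problem (50 epochs suffice for the 60-slide synthetic cohorts; the
production default is 250). The checkpoint with the best validation AUROC
is restored at the end.

## Survival modeling

The survival head maps an embedding to Weibull parameters through
positivity-guaranteeing activations: scale `λ = exp(a)`, shape
`κ = softplus(b)`. Right censoring enters through the censored negative
log-likelihood — events contribute
`−[log(κ/λ) + (κ−1)log(t/λ) − (t/λ)^κ]`, censored records the cumulative
hazard `(t/λ)^κ`. The shape parameter lets the model express increasing,
decreasing or constant hazards.

The *survival index* of a prediction is the Weibull median
`λ·(ln 2)^{1/κ}` (the mean `λ·Γ(1+1/κ)` is available by option). Cohorts
are split into predicted longer-/shorter-term groups at the *median index
of the training fold*, applied frozen to held-out data — computing the
threshold on the evaluation set would leak. Ties fall to the shorter-term
side.

The desk-scale survival model (`LinearWeibullModel`) is a linear covariate
head `λ_i = exp(w·x_i + b)` with a global shape, trained full-batch with
RMSprop under cosine lr decay (constant-lr RMSprop oscillates around the
optimum; with decay the fit matches lifelines' Weibull MLE to ~1e-5).
Cross-validation is slide-level 5-fold; event-free folds are merged into a
neighbor.

## Evaluation

AUROC (Mann–Whitney, ties ½; scikit-learn), Harrell's c-index (comparable
pairs under right censoring, risk ties ½; lifelines), Kaplan–Meier
product-limit curves and the two-group log-rank test with two-sided
chi-square(1) p-values (lifelines). The package wraps these behind its own
operation surface to add the input-validation and error contracts the
pipeline relies on (single-class AUROC, no-comparable-pairs c-index and
zero-variance log-rank raise). Independent brute-force enumerations of all
four metrics live in the test suite and agree exactly on instances of ≤ 8
samples.

## Interpretation

*Occlusion importance* of a tile region is the signed change in the
predicted target-class probability when the region's tiles are removed from
the bag. Removal (rather than graying pixels) is the faithful occlusion for
a model that consumes tile features; single-tile slides fall back to the
uniform prior. For additive-logit surrogates the importance ordering equals
the ordering of per-tile contributions, which the tests verify analytically.

*Concept scores*: a 7-concept patch classifier (tumor epithelium, stroma,
lymphocytes, smooth muscle, mucus, adipose, debris) scores the
high-importance regions. The classifier is a frozen random-filter
convolutional stage followed by a trained multinomial logistic head — a
convolutional classifier whose conv stage is fixed by seed, chosen so
training is seconds on CPU and exactly reproducible; on the procedural
textures it reaches 100 % held-out accuracy. Regions with importance above
0.7 are selected; by default the threshold lives on the min–max-normalized
importance scale, because raw probability changes from removing a single
tile rarely exceed 0.7 (a `raw` mode thresholds the signed change
directly). Each selected region contributes `importance × concept
probability`; per-concept sums are scaled so the top concept reads exactly
100. An empty selection yields all-zero scores with a warning.

Heatmaps blend a diverging color map (`coolwarm`, symmetric [−1, 1] norm,
neutral at zero) over the slide at α = 0.4 with an embedded legend bar;
rendering is deterministic.

## Synthetic data: what it emulates and what it does not

Concept textures are procedural — dots, stripes and blobs with
concept-specific density, frequency and size, composed in stain-concentration
space and rendered through the OD forward model with Gaussian OD noise.
They are linearly separable in simple filter statistics *by construction*.
Slides are flat rectangular layouts of such regions; labels are planted
deterministically (positive iff ≥ m tumor regions). Survival cohorts draw
standard-normal covariates, Weibull event times with covariate-dependent
scale, and uniform censoring times whose upper bound is calibrated by
bisection to hit the requested censoring fraction.

Passing tests on this data establishes that the machinery is correct:
stain recovery inverts the forward model, the MIL pipeline finds planted
signal and attends to it, the Weibull head recovers generating parameters,
null cohorts calibrate to chance. It does **not** establish performance on
real histopathology: real tiles are not linearly separable, real
stain/scanner variation is richer than a 3×2 matrix swap, tissue artifacts
(folds, pen marks, blur) are absent, and real survival signal is far weaker
than the planted coefficient. Numbers reported on synthetic cohorts are
sanity bounds, not performance claims.

## Numerical choices

- log-argument clamping at 1e-12 (bag loss, Weibull likelihood).
- k-means: 10 restarts; assignment ties to the lower index.
- Stratification ties to shorter-term; all-identical indices are flagged.
- Split rounding: floor for val/test within each label stratum, remainder
  to train; re-drawn (≤ 20 times) if a class is missing from a partition.
- Determinism: all randomness flows through explicit seeds (generator,
  model init, dropout, shuffling, k-means); eval-mode forwards are exactly
  reproducible. Training determinism assumes the single-threaded BLAS
  behavior of the default build.

## Known limitations

- The NN core is a compact numpy autodiff engine; it is exact but not fast.
  Production-scale slides (thousands of 1000-px tiles, 2048-d features,
  512-d transformer) would need a GPU framework behind the same interfaces.
- The shipped backbones are untrained random-feature extractors: adequate
  for separable synthetic textures, far below a pretrained residual network
  on real tissue. The backbone interface accepts any callable.
- One model per task (no multi-label heads), no ensembling, no Cox or
  discrete-time alternatives, no competing risks, flat images only (no
  pyramidal WSI containers).
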