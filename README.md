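# moma

Weakly-supervised prediction of slide-level molecular labels and
right-censored survival outcomes from whole-slide histopathology images,
with occlusion-based interpretation — implemented end-to-end and exercised
entirely on synthetic slides and cohorts with known ground truth.

## Who this is for

Computational-pathology researchers who want a tested, CPU-runnable
reference implementation of the cluster-structured attention-MIL recipe:
tile → stain-normalize → embed → cluster → transformer-encode → attention-
pool → predict, trained with a dual bag/instance objective, plus a Weibull
survival head and an occlusion/concept explanation stack. Every stage is an
importable function with a contract and a test; a thin `moma` CLI chains
them into a pipeline.

## The model

A slide is a *bag* of tile feature vectors `{h_1..h_n}` with one label.
Tiles are grouped into K = 10 k-means microenvironment clusters; each
cluster's tiles are encoded as an unordered token set by a transformer
(512 hidden / 8 heads / 2048 MLP / dropout 0.1 in the production
configuration), pooled by gated attention

    a_i ∝ exp{ w^T ( tanh(V h_i) ⊙ σ(U h_i) ) },   Σ a_i = 1,

to a cluster vector, and the cluster vectors are attention-pooled again to
the slide embedding. Classification trains on

    L = −w_y log p_y  +  mean_i ℓ_τ(z_i),    ℓ_τ(z) = τ·log(1+e^{(1−z)/τ}),

the first term a bag cross-entropy with inverted class weights
`w_c = N/(C·n_c)`, the second a smooth-SVM instance loss on tiles of the
top-3 / bottom-3 attention-ranked clusters (positive / negative
pseudo-labels). Survival replaces the head with Weibull parameters
`λ = exp(a)`, `κ = softplus(b)` trained on the censored likelihood; a
patient's survival index is the predicted median `λ (ln 2)^{1/κ}`, and
cohorts are stratified at the training-fold median index (Kaplan–Meier,
log-rank, c-index in `moma.evaluation`). Explanations: per-region occlusion
importance (change in predicted probability when the region's tiles are
removed from the bag) and seven pathology-concept scores scaled to
[0, 100]. Details and assumptions: [docs/methods.md](docs/methods.md).

## Worked example

`examples/` holds one short script per capability. Training the MIL
classifier on a 30-slide planted cohort
(`python examples/train_mil_classifier.py`) prints:

```
held-out AUROC: 1.000
median attention on planted tumor tiles: 0.092 vs other tiles: 0.0314
```

The label was planted as "slide contains ≥ 2 tumor-texture regions"; the
model recovers it perfectly from slide-level supervision alone, and its
tile attention concentrates on exactly the planted regions. Survival
modeling (`python examples/survival_analysis.py`):

```
recovered shape kappa = 1.476  (generating value 1.5)
recovered coefficient = 1.220  (generating value 1.2)
fresh-sample c-index: 0.812
median-split log-rank: chi2 = 528.2, p = 6.87e-117
```

The censored-likelihood fit recovers the generating Weibull parameters and
the median-index split separates real survival curves. The other scripts
demonstrate stain-matrix recovery / normalization and the occlusion +
concept-score explanation stack.

The same pipeline as a shell workflow:

```bash
moma simulate --out run/ --n-slides 60
moma preprocess --workdir run/
moma features --workdir run/ --backbone tiny
moma cluster --workdir run/
moma train-classifier --workdir run/ --epochs 50
moma interpret --workdir run/
```

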