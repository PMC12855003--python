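# Methods

## Model

The network has two MLP modules. The **compressor** maps a control cell's
log-normalized expression vector (length |G|) through hidden layers of
width 2048 and 512 into a linear bottleneck of width 64. The **generator**
takes the bottleneck state concatenated with the perturbation embedding
(1,536-dimensional for the reference GenePT-style tables; the dimension is
inferred from whatever table is supplied) through one hidden layer of
width 2048 to a linear output of length |G|. Hidden layers are ordered
affine → batch-norm → SELU; layer-norm and AlphaDropout exist in the code
but are off by default (dropout rate 0). The embedding is an external
frozen input — there is no trainable lookup, and the table object is
read-only with a checksum to prove it.

Choices the architecture description leaves open, fixed here:

- **Bottleneck is purely linear** (no activation or normalization); a
  `bottleneck_nonlinear` flag restores the hidden-layer treatment.
- **Batch-norm precedes the activation**, the conventional ordering.
- **The output layer is linear and unclipped**: inputs are log-space
  values, and slightly negative predictions are meaningful residuals
  rather than errors.
- **Weight initialization** is LeCun-normal (the self-normalizing-network
  default for SELU), seeded from the config so two builds with the same
  seed are bit-identical.

The network, backpropagation, batch/layer normalization, Adam and
gradient clipping are implemented directly in numpy (`scouter.nn`); a
finite-difference test validates the full analytic gradient end to end.
Batch-norm uses biased batch variance for both normalization and the
running buffers (momentum 0.1, eps 1e-5); eval mode uses the running
statistics only, so eval-mode outputs are deterministic and
batch-independent (up to BLAS kernel reordering on the order of 1e-15).

## Loss

For a batch of N triplets covering M unique perturbations t₁..t_M:

- autofocus: (1/M) Σₘ (1/(|N_tₘ|·|G|)) Σ_{i∈N_tₘ} Σ_g |x_ig − x̂_ig|^(2+γ)
- direction: same normalization over [sign(x_ig − c_ig) − sign(x̂_ig − c_ig)]²
- total: L = L_autofocus + λ·L_direction.

Conventions: sign(0) = 0, so each direction entry is in {0, 1, 4};
|·|^(2+γ) rather than (·)^(2+γ) so non-even exponents are well-defined
(identical on the searched grid γ ∈ {0, 2}). The direction term is
piecewise constant in x̂, so by default gradients flow only through the
autofocus term while the *reported* loss is exact; an optional smooth
surrogate replaces the predicted sign by tanh(α·(x̂ − c)) in the gradient
only. The paired control cᵢ in the direction term is the triplet's own
random control, exactly as the formula reads, not a mean control.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999) at an initial learning rate from
{0.001, 0.005, 0.01}, decayed by ×0.9 each epoch; batch size 256; at most
40 epochs; gradient global-norm clipped at 1.0; early stopping when the
best-so-far validation loss fails to improve by more than 0.001 for 5
consecutive epochs; the best-validation weight snapshot (parameters *and*
batch-norm buffers) is restored at the end.

Pairing: each epoch pairs every perturbed training cell once with a
control drawn uniformly with replacement, re-drawn each epoch, so over
training the sampler ranges over the full n₀·Σₖnₖ pair space. The
validation pairing is drawn once per run from its own seed so the early
stopping criterion compares identical data across epochs. The last
incomplete batch of an epoch is kept. Controls are shared across phases
because splits partition perturbations, never cells.

Grid search trains one model per (γ ∈ {0,2}) × (λ ∈ {0.01, 0.05, 0.1,
0.5}) × (lr ∈ {0.001, 0.005, 0.01}) × split and picks the point with the
lowest mean best-validation loss. Published per-dataset winners are
shipped as presets (γ = 0 everywhere; Dixit λ=0.05/lr=0.01, Adamson
λ=0.01/lr=0.001, Norman λ=0.05/lr=0.001, Replogle K562 and RPE1
λ=0.5/lr=0.001).

Splits are over perturbations: `test20_val10` holds out ⌊20%⌋ for test and
splits the rest 90/10 (validation rounded up, every set ≥ 1);
`dixit_801010` uses 80:10:10 for perturbation-poor datasets. Two-gene
test perturbations are stratified as seen2/seen1/seen0 by how many of the
pair's genes occur anywhere in the training perturbations.

## Prediction and evaluation

A prediction samples K = 300 control cells uniformly with replacement
(well-defined even when n₀ < K), runs the eval-mode forward pass with the
composed embedding, and keeps all K profiles plus their mean. Batch
prediction derives one seed per perturbation from the master seed via
SHA-256, making results independent of request order.

Evaluation compares, per perturbation, the mean observed profile of its
held-out cells against the prediction's mean profile, with the mean
control profile as reference, restricted to the top-K DEGs (K = 20).
The default DEG ranking is |mean perturbed − mean control| descending with
ties broken by gene index; precomputed DEG lists can be supplied and take
precedence. Reported aggregates are medians per subgroup and overall with
50% bootstrap confidence intervals — the 25th/75th percentiles of the
bootstrap distribution of the median over perturbations (1,000 resamples).
A perturbation whose metric is undefined (no true change over its DEGs,
or a zero-variance change vector — the no-change baseline always has an
undefined 1 − PCC) is flagged and excluded from that metric's aggregates
only.

## Synthetic data

The simulator draws, from one seed: per-gene embeddings E(g) with i.i.d.
N(0, 1/dim) coordinates (unit expected norm); a linear effect map W with
i.i.d. N(0, effect_scale²) entries; a baseline profile μ with
Exponential(1) entries (log-space-like, nonnegative, right-skewed); and
Gaussian observation noise. A perturbation's true effect is
δ(g) = mask_g ∘ (W·E(g)); cells are μ + δ + ε with ε ~ N(0, noise_sd²).
Two-gene effects are δ(g₁) + δ(g₂) plus an optional N(0, interaction_sd²)
interaction (exactly additive at interaction_sd = 0).

Defaults — the package's study conditions — are 200 genes, 40 single
perturbations × 100 cells, 2,000 controls, dim 32, effect_scale 1.0,
noise_sd 0.2 (typical per-gene effects ≈ 0.8, i.e. ≈ 4× noise), density
(sparsity) 1.0, purely additive doubles. **Why density 1.0:** with a
per-perturbation *random* mask of density s, the mask of an unseen
perturbation is unpredictable from its embedding, and the Bayes-optimal
prediction is the mask-marginalized effect s·W·E(g); on the top DEGs
(which are masked-in genes) the achievable normalized MSE is then bounded
below by (1−s)², e.g. 0.81 at s = 0.1, regardless of model quality. Dense
effects keep the embedding → effect map exactly linear, which is the
property — attributed to informative text embeddings — that makes
extrapolation to unseen perturbations possible at all. Sub-unit sparsity
remains available for exercising DEG selection and loaders.

What the simulator does not emulate: count-level noise (a Poisson/log1p
mode exists for loader tests only), guide-assignment errors, batch
effects, dropout structure, or nonlinear gene regulation. Passing the
recovery tests therefore shows the implementation is correct and the
architecture can exploit embedding-linear structure; it does not certify
accuracy on real Perturb-seq data.

## Problem sizes for the shipped checks

The end-to-end recovery checks and `scripts/acceptance.py` run on the
default simulation above with a proportionally scaled network —
compressor 256/128 → bottleneck 32, generator 256, lr 0.005, λ = 0.05,
γ = 0 (`scouter.model.synthetic_config`) — because the full-scale widths
target ~5,000-gene panels. Training one such model takes well under a
minute on a single CPU; the single-gene run holds out 20% of
perturbations (median top-20-DEG normalized MSE ≈ 0.12 vs the baseline's
exact 1.0), and the two-gene run holds out 10 additive doubles in the
seen2 setting (median ≈ 0.005, reflecting both the larger effect norms of
doubles and exact additivity).

## Known limitations

- The direction loss contributes no gradient by default (exact sign
  form); it still influences model selection via validation loss and the
  λ grid.
- Training is single-threaded numpy; large real datasets (~5,000 genes,
  10⁵ cells) are feasible but slow compared to a GPU implementation.
- The loader assumes upstream preprocessing (log-normalization, multiplet
  removal); it warns on count-like input but never transforms data.
- Bootstrap CIs treat perturbations as exchangeable units; with very few
  test perturbations the 50% CI is close to degenerate.
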