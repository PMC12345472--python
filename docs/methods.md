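# Methods

## The problem

A sheep's face changes dramatically between 1 and 12 months of age: the head
grows (fastest before month 4), pelage tone shifts, and from around month 8
fur increasingly covers the face. A recognition model trained on lamb faces
therefore degrades on the same animals months later. This package implements
an age-invariant identification pipeline that splits the learned face
embedding into an *age code* and an *identity code*, and trains the two
toward statistical independence, so that identification relies on features
that survive growth.

## Model

**Backbone.** A residual bottleneck network with squeeze-and-excitation (SE)
channel recalibration. Each SE gate computes
`g = sigmoid(W2 relu(W1 GAP(F)))` with a reduction-16 bottleneck and rescales
the channels of the feature map `F`. Two presets ship:

| preset | stage widths | blocks | input | embedding |
|---|---|---|---|---|
| `fe_net50` | 256/512/1024/2048 | 3/4/6/3 | 224×224 | 2048 |
| `fe_net_tiny` | 32/64/128/256 | 1/1/2/1 | 64×64 | 256 |

`fe_net_tiny` is the desk-scale reduction used throughout the tests: a 3×3
stride-1 stem preserves resolution at 64×64 and the four stages each halve
the spatial size, ending in a 256×2×2 map (stride 32 overall). SE gates sit
after the last bottleneck of each stage by default (`every_block` is
available for ablation). Initialization is He fan-out for convolutions with
zero-initialized final BN scales in each residual branch.

**Attention (ECBAM).** The age branch runs the final feature map through an
efficient channel+spatial attention block: global average- and max-pooled
channel statistics pass through two *unshared* 1-D convolutions along the
channel axis (kernel size from the `floor((log2 C + 1)/2)`-rounded-odd rule,
e.g. 5 at C=256, 7 at C=2048), are blended by a trainable scalar α
(initialized 0.5, used as the convex pair (α, 1−α)) and squashed by a
sigmoid; a 7×7 convolution over the channel-mean and channel-max maps yields
the spatial gate. Channel attention is applied first, spatial attention
second; the block only attenuates. A classic CBAM (shared two-layer MLP
channel gate) is included for ablations.

**Decoupling.** The age code is `x_age = BN(MLP(GAP(ECBAM(F))))` (two-layer
MLP, widths d→256→128). A residual map `r = MLP_res(x_age)` (128→256→d)
returns to embedding space, and the identity code is `x_id = x − r`. The
bundle stores `x` as the sum `x_id + r` evaluated once, so the conservation
invariant holds bitwise; the difference to the raw pooled embedding is one
float rounding at most. The BatchNorm on the age code is load-bearing: the
raw MLP output has per-dimension scale ~0.02, which starves every map that
consumes it.

**Correlation module.** Each code passes through a one-hidden-layer
perceptron kernel map (hidden 64); projection vectors reduce the mapped codes
to scalars whose batch Pearson correlation ρ is the decorrelation signal,
with `L_id,grow = ρ²` (mean over pairs when several projection pairs are
kept; default 8). Degenerate batches (zero variance on either side) define
ρ = 0 and contribute no gradient.

## Objectives

* Identity: CosFace — unit-normalized embeddings and class vectors, margin
  `b` subtracted from the true-class cosine, scale `s`, softmax
  cross-entropy. Defaults `s = 30`, `b = 0.35`.
* Age: half-mean-squared error `(1/2m) Σ (F_age(x_age) − z)²` on a linear
  regressor over the age code, with raw month labels 1–12 (an RMSE reporting
  helper exists separately; the loss is the half-MSE as stated).
* Joint: `L_w = L_id + α·L_grow + β·L_id,grow` with defaults α = 0.01,
  β = 1 — the grid-search optimum (α ∈ {0.005, 0.01, 0.015, 0.02},
  β ∈ {0.5, 1}).

## Training

Each iteration plays one round of a min-max game:

1. **Adversary.** The correlation module takes `adversarial_ratio` (default
   1) SGD-ascent steps on ρ² (kernel maps, 10× base learning rate, L2 pull
   toward zero realizing a Gaussian prior), and its projection vectors are
   then set to the exact ridge-CCA maximizers computed in closed form over a
   replay buffer of recent detached codes (~512 samples). The buffer matters:
   CCA solved on a 32-sample minibatch with 64-dimensional kernel features is
   rank-deficient and reports spurious ρ ≈ 1. By the envelope theorem,
   holding the solved projections fixed leaves the encoder's gradient
   correct.
2. **Encoder.** One SGD step (momentum 0.9, weight decay 1e-4, base lr 1e-3)
   on the joint loss for everything else.

Two auxiliary terms stabilize the decoupling, both package design choices in
a region the source architecture leaves unspecified:

* **Residual fitting.** `MLP_res` is additionally regressed (on detached
  inputs/targets) toward the per-age batch mean of the embedding. The
  subtraction `x − E[x|age]` is exactly what annihilates the linearly
  decodable age component (verified with an oracle per-age-mean probe), but
  the joint loss alone leaves the residual map essentially constant — the
  age-mean component is only ~2% of the embedding variance. The residual map
  gets a 10× learning-rate group for the same reason, as does the (convex,
  tiny) linear age readout, whose effective rate would otherwise be throttled
  by α.
* **Schedule.** One warmup epoch then cosine decay. A constant rate leaves
  the margin-scaled softmax oscillating at this problem size.

Training batches receive the four-way augmentation policy *stochastically*
(each image kept, photometric-jittered ±20%, noise-injected σ = 0.02, or
rotated ±15°, with equal probability), plus an independent random rescale
(±30%, probability 0.5) — the standard random-resized-crop-style scale
jitter of recognition pipelines. The static ×4 expansion (the same four
transforms materialized per image) remains available in the generator for
dataset construction. Validation accuracy is tracked per epoch on a
256-sample subsample (full validation split on the final epoch).

Grid search trains every combination, selects by validation top-1 accuracy
(ties: lower validation loss, then smaller learning rate), and never reads
the test split — the cohort object records split accesses and the search
asserts the audit.

## Synthetic cohorts

No public longitudinal sheep-face dataset exists, so the package renders its
own. Each individual owns an eye spacing (0.35–0.60 of head width), a nose
offset, a coat-pattern seed, one of four markings (plain/blaze/forehead
patch/cheek patch) and a base coat hue — all drawn independently of age.
Age drives three factors:

* head scale `s_max (1 − e^{−age/τ})` with τ = 2.5 months, putting ~80% of
  growth before month 4;
* a linear pelage-lightness drift (0.018 value units/month about month 6);
* band-pass fur texture with amplitude `0.035·(age − 8)⁺`, zero before
  month 8.

Facial geometry and coat pattern are placed in head-local coordinates, so
they scale with growth but keep identity-specific shape. Nuisance is applied
last: luminance gain/bias, in-plane rotation, Gaussian noise. Everything is
a pure function of the seeds, so renders reproduce bit-for-bit. The default
test cohort is 20 identities × 12 months × 8 repeats at 64×64.

Split protocols: *age-based* (train 1–4, validation 5–8, test 9–12 months —
the primary protocol) and *id-based* (~44:5:6 proportions of individuals,
pairwise disjoint).

What the generator does **not** emulate: out-of-plane pose, occlusion,
background clutter, camera optics, within-individual coat change beyond the
fur term, and open-set identities. Passing the end-to-end tests therefore
shows the pipeline recovers planted structure under controlled factors, not
field performance on real animals.

## Evaluation

Identification is nearest-class-vector on the unit-normalized identity code.
The report covers precision/recall/F1/accuracy from pooled one-vs-rest
counts, top-1 accuracy, mAP@0.5 (each record's face crop box doubles as the
predicted box — a classification-only reduction under which the IoU term is
exact), two equal-error-rates (`eer_eq11`, the pooled misclassification rate
as printed in the source metric list, and `eer_roc`, the FAR = FRR crossing
on cosine-similarity verification pairs with linear interpolation), FAR/FRR
curves, and per-age-group tables (1–3, 4–6, 7–9, 10–12 months).

**Leakage diagnostics** quantify decoupling quality: ordinary-least-squares
age predictors fitted on `x_age` and on `x_id`, reported as two-fold
*cross-fitted* R² (fit one half, score the other) — in-sample OLS with
128–256 features on ~2k samples is optimistic by roughly p/n even on noise.
Negative R² is clipped to 0 and flagged. The diagnostics default to the full
cohort: under the age-based protocol each split spans only four months, far
too little age variance for the regression to mean anything (on the test
split, months 9–12, growth has essentially saturated).

Saliency maps are gradient-weighted class-activation maps on the final
feature map (gradients of the scaled cosine logit, spatially averaged into
channel weights, rectified, bilinearly upsampled, max-normalized).

## Known limitations

* A linear probe can still decode age from the identity code even when
  identification is accurate across ages. Two structural reasons: the
  between-window age signature at months 5–12 is driven by factors the model
  never observes during training (fur onset, saturated scale), so removing
  it would require extrapolation; and aging directions are partly
  *identity-specific* (lightness drift interacts with base hue, fur pattern
  with the coat seed), while any deployable residual subtraction must be
  identity-agnostic — the identity-specific component is irreducible by
  construction. The subtraction itself is verified in oracle form: replacing
  the learned residual with the true per-age mean embedding removes all
  linearly decodable age.
* The measured projection correlation between the two codes stays high at
  convergence because both codes are functions of the same image and share
  identity and nuisance content; the closed-form adversary finds whatever is
  shared, not only age. A lagging minibatch-SGD adversary reports much
  smaller final correlations — an artifact of adversary weakness, not of
  independence. An experimental `age_code_purity_weight` penalizing identity
  content in the age code is available but off by default (it did not reduce
  the correlation and costs accuracy).
* The numpy autodiff engine is single-threaded and sized for the tiny
  preset; `fe_net50` builds and runs forward passes but is not practical to
  train in this engine.
* mAP@0.5 here reduces to classification mAP because the pipeline performs
  no detection; a real detector is out of scope.
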