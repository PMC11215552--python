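# Methods

## Model

`pdsp` predicts, for a drug pair ⟨i, j⟩ in a context *k*, the pair's Bliss
synergy score (regression) and each drug's sensitivity class (binary
classification, 1 = sensitive) from the drugs' chemical-descriptor vectors
and the context's gene-expression profile.

Three fully connected sub-networks compose the model:

- **Drug encoder (DEN).** Input `concat(d, c)`; a stack of FC layers with
  ReLU activations, dropout after every layer *including the final linear
  layer*, output `h ∈ R^m`. One parameter set serves both drug positions —
  weight sharing is structural (one storage), not synchronized copies, so
  the two drugs of a pair are treated identically by construction.
- **Drug decoder (DDN).** `h →` FC/ReLU/dropout stack `→` final linear
  layer emitting a sensitivity *logit*; the logistic transform is applied at
  prediction time and inside the loss in a numerically stable
  softplus-based form. Shared between positions like the encoder.
- **Synergy head (SAN).** `concat(h_i, h_j) →` FC/ReLU/dropout stack `→`
  linear Bliss score.

Concatenation makes the raw SAN output order-dependent. Order-invariance is
enforced two ways: during training every pair is presented in both orders
(augmentation), and at prediction time the two orders are averaged, which
is *exactly* symmetric in IEEE arithmetic (float addition is commutative),
so `predict(i, j, c).y_hat == predict(j, i, c).y_hat` bitwise.

### Loss

```
L = L_reg + λ · (wBCE_i + wBCE_j)
L_reg  = (1/N) Σ (y − ŷ)²
wBCE   = −(1/N') Σ [λ₁ s log ŝ + λ₂ (1−s) log(1−ŝ)]
```

λ defaults to 10. λ₁/λ₂ default to inverse class frequencies of the
training sensitivity labels, renormalized to mean 1 (the standard imbalance
correction); they can be set explicitly. Pairs without a sensitivity label
for a position are masked out of that position's wBCE, and each term's N'
counts only unmasked entries; a term with every entry masked contributes
zero. Probabilities are clipped to [1e−7, 1−1e−7].

### Training

Mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with global-norm gradient
clipping at 5. Optional decoupled weight decay and per-epoch learning-rate
decay are available and off by default. The snapshot with the best
validation metric (`val_total_loss` or `val_mse`) is returned; training
stops after `patience` epochs without improvement. Given a seed,
single-threaded training is bitwise reproducible: all randomness
(initialization, shuffling, dropout masks) flows from one
`numpy.random.Generator`.

The forward/backward passes and the optimizer are implemented in numpy with
analytic gradients; the test suite verifies them against central finite
differences on a ≤ 50-parameter model at 1e−4 relative tolerance (with
parameters jittered off the ReLU kink, where a central difference and the
subgradient legitimately disagree).

### Personalization

Patients have expression profiles and single-drug sensitivity labels, but
no synergy labels. Fine-tuning therefore optimizes only the classification
term (wBCE through DEN → DDN) and the synergy head is frozen — structurally:
SAN's parameters are never handed to the optimizer and receive no gradient.
Two strategies:

1. **Pooled** (`finetune_all_patients`): one model fine-tuned on all
   patients' labels, used for every patient.
2. **Per patient** (`finetune_per_patient`): an independent run per patient,
   each starting from the same pre-trained weights and seed.

DDN is trainable during fine-tuning by default (`finetune_train_ddn=False`
freezes it; the encoder gradient flows through DDN either way). Fine-tuning
uses a fixed epoch budget (default 50) rather than early stopping, because
patient label sets (hundreds of labels) are too small to spare a validation
split; the default fine-tune learning rate is 3e−4 with batch size 32 —
smaller batches were chosen so per-patient runs (≈ 200 labels) get a
comparable number of optimizer steps to pooled runs, keeping the two
strategies' budgets commensurate.

## Preprocessing

- **Replicate averaging**: synergy replicates of the same canonical
  (pair, context) triple are arithmetic-averaged after pair
  canonicalization, so ⟨A,B⟩ and ⟨B,A⟩ replicates merge; output is sorted
  by triple and the operation is idempotent.
- **Binarization**: sensitive ⇔ ln IC50 strictly < −2 (a value of exactly
  −2 is resistant); synergistic ⇔ Bliss strictly > 0 (exactly 0 is
  antagonistic, since synergy requires a positive score).
- **Gene alignment**: expression matrices from different platforms are
  reconciled by gene-set intersection only (sorted order); missing genes
  are never imputed.
- **Quantile normalization** is asymmetric: the cell-line training matrix
  defines the reference quantile vector (per-rank means of its sorted
  columns) and every profile — cell line or patient — is mapped onto it by
  within-column rank. Tie runs receive the mean of the quantiles at the
  ranks the run occupies; untied values take their reference quantile
  exactly. Referencing to the large matrix avoids fitting quantiles on a
  3-sample patient matrix and keeps held-out data out of the reference. A
  joint fit is available by passing the concatenated matrix as reference.

## Splitting

Leave-drug-combination-out: unique canonical pairs (lexicographic order on
drug ids) are shuffled with the split seed and allocated 60/20/20 at the
*pair* level by largest-remainder rounding (remainder ties break on split
order), and every record follows its pair regardless of context. This is
deliberately conservative: a pair measured in many cell lines lands wholly
in one split.

## Evaluation

Regression: MSE, Pearson, Spearman (average ranks on ties); correlations on
constant vectors are an error, never a silent 0. Classification of synergy
uses the *regression output* thresholded at 0 — no separate classifier is
trained. Rank metrics: AUC (trapezoidal, equal to the Mann–Whitney
statistic under ties), partial AUC over FPR ≤ 0.1 with McClish
standardization `0.5·(1 + (A − A_min)/(A_max − A_min))` so a random
classifier scores 0.5 (raw-area mode available), and AUPR as the area under
the step-wise precision envelope. Thresholded metrics (precision, recall,
F1, balanced accuracy, Cohen's κ) come from confusion counts with explicit
conventions: an undefined ratio (zero denominator) is reported as 0, and κ
is 0 when chance agreement saturates — degenerate one-class predictors are
a case this analysis must compare, not crash on. Rank metrics require both
classes and raise otherwise; thresholded metrics remain available.

## Synthetic world

The generator plants a shared latent structure:

- drug latents `u_i = P d_i`, context latents `v_k = Q c_k` (unit-norm-row
  projections of standard-normal features);
- sensitivity logit `⟨u_i, v_k⟩ + ε`, binarized at 0; cell-line sensitivity
  is exported on the ln IC50 scale (`−2 − logit`) so the preprocessing
  threshold reproduces the planted labels;
- synergy `y = ⟨u_i ⊙ u_j, R v_k⟩ + β(⟨u_i, v_k⟩ + ⟨u_j, v_k⟩) + ε`,
  symmetric in the drugs by construction, with β = 0.5 — a multiplicative
  pair interaction on top of an additive single-drug term, so that
  single-drug response genuinely informs (but does not determine) synergy;
- patients are cell-line-like expression vectors plus a mean shift of
  magnitude 2.0 along a random per-patient unit direction, emulating the
  cohort/platform shift between cell-line and patient measurements.

Defaults: 300 drugs, 20 cell lines, 3 patients, 64 drug-descriptor and 64
expression dimensions, latent dimension 8, 5000 unique (pair, cell line)
records (≈ 10% receiving a replicate), 200 sensitivity labels per patient,
and a 40-pair evaluation panel per patient (large enough for stable
balanced-accuracy estimates on three patients while staying desk-scale).
Synergy noise defaults to the level at which the planted signal explains
80% of observed variance. Everything is deterministic per seed.

What the generator does *not* emulate: realistic descriptor marginals or
correlations, expression covariance structure, dose–response curve shapes,
or measurement batch effects. Passing tests on this world demonstrate the
mechanics of the workflow (masked multi-task training, frozen-head
transfer, the benefit of personalization under domain shift) — not
performance on real pharmacogenomic data.

## Desk-scale configuration

The architecture defaults (`DEN [1024, 512] → m = 256`,
`DDN [128, 64] → 1`, `SAN [512, 256] → 1`, dropout 0.2) are sized for
real descriptor/expression data. The bundled benchmark uses a smaller
funnel matched to the synthetic world's 64-dimensional features —
`DEN [128, 64] → m = 32`, `DDN [32, 16]`, `SAN [64, 32]`, dropout 0.2 —
trained up to 300 epochs with patience 40 on `val_mse`. These sizes were
selected by validation performance, which is also how the model's
hyperparameters are meant to be chosen on real data.

## Known limitations

- On the synthetic world, the trained model recovers the *additive*
  (single-drug) component of the planted synergy well but captures little
  of the *multiplicative* pair interaction: held-out Pearson against the
  noiseless planted signal plateaus around 0.5, whereas a predictor with
  access to the true latents reaches ≈ 0.9. Diagnostics show why: the two
  scalar training signals (one Bliss score, one logit per drug) do not
  force the encoder to preserve the full drug latent, so the synergy head
  has no bilinear structure to exploit for unseen pairs. This is a genuine
  property of the encoder–concatenation–MLP design at this data scale, not
  an optimization bug — wider/deeper variants, dropout and weight-decay
  sweeps, learning-rate schedules and seed ensembles all land in the same
  range.
- Fine-tuning quality degrades gracefully but noticeably when the patient
  shift is large relative to what quantile normalization can absorb
  (normalization equalizes marginals; a directional shift also permutes
  within-profile ranks, which only fine-tuning can address).
- Checkpoints store float64 arrays; models are small (≈ 10⁵ parameters at
  desk scale) so this is cheap, but the format is not meant for very large
  models.
- The CLI's `predict` requires every context named in the pairs table to be
  present in the supplied expression matrix; there is no nearest-neighbour
  fallback for unseen contexts.
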