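# Methods

## Setting and labels

The input is a wide per-variant annotation table: numerical scores
(predictor outputs, conservation metrics, allele frequencies), categorical
annotations (consequence classes, review statuses), and free-text fields in
which only the presence of certain keywords is informative. A label column
carries one of six ACMG-style categories. The package maps these to a binary
benign/pathogenic task with a hard/soft partition:

| category            | binary target | hardness |
|---------------------|---------------|----------|
| Benign auto         | 0             | hard     |
| Benign              | 0             | hard     |
| Likely Benign       | — (hint 0)    | soft     |
| VUS                 | —             | soft     |
| Likely Pathogenic   | — (hint 1)    | soft     |
| Pathogenic          | 1             | hard     |

Hard rows are the only supervised ground truth. The likely-* hints are
advisory metadata only: soft rows receive training labels exclusively through
pseudo-labeling, so a Likely Pathogenic row that the model confidently calls
benign is trained as benign.

Splits are 70/15/15 train/validation/test, stratified over the **six
original categories** (not the binary target), because the final evaluation
is a per-category confusion matrix and each category's share must be stable
across splits. Within each category the split counts follow largest-remainder
apportionment (within one row of exact) with seeded random assignment;
categories with fewer than 3 rows fall where the remainders put them, which
in practice is the training split first.

## Preprocessing

Fitted on training rows only; application uses fitted parameters and never
recomputes statistics.

1. **Missingness filter**: drop a feature column iff its training missing
   fraction is *strictly greater* than 0.25 (a column at exactly 25% is
   kept).
2. **Imputation** (numerical): with a per-column domain hint
   (`low_is_worst` / `high_is_worst`, e.g. allele-frequency-like columns),
   fill at the observed extreme in the hinted direction (worst-case fill);
   otherwise a moment heuristic decides: |skewness| < 1 **and** excess
   kurtosis < 3 ⇒ mean, else median. The heuristic is deterministic and
   cheap; no distributional test is run.
3. **Constant removal**: columns constant after imputation are removed here
   because no scaler is defined for them.
4. **Scaling**: the same moment heuristic selects standard scaling
   (train mean 0, sd 1) for normal-looking columns and min-max (train range
   → [0,1], both endpoints attained) otherwise. Apply-time values outside
   the training range pass through **unclipped** (>1 or <0), preserving
   information rather than saturating it.
5. **Encodings**: ordinal columns use their declared ranking as 0-based
   codes; nominal columns get integer codes destined for embeddings (an
   optional per-column one-hot mode emits 0/1 numerical columns instead);
   keyword columns become 1 iff any configured keyword occurs
   case-insensitively as a substring (missing ⇒ 0). Missing categorical
   values are their own category; categories unseen at fit time map to a
   reserved unknown code (the embedding table carries one extra row for it),
   so apply never fails on new data.
6. **Variance filter** (after scaling/encoding): scaled numerical columns
   with variance ≤ 1e-4 are dropped (≤, so a column at exactly the threshold
   is dropped); encoded categorical columns whose majority category exceeds
   1 − threshold are dropped.

Coercion failures while reading (e.g. `"abc"` in a numerical column) degrade
to missing with a logged count; the default missing tokens are
`"", "NA", "N/A", ".", "-"`, configurable per column. The fitted plan
serializes to a single JSON document and round-trips exactly.

## Model

Feature Tokenizer Transformer with a single-logit sigmoid head:

* Tokenizer: numerical feature j ⇒ `b_j + x_j·W_j` (per-feature weight and
  bias vectors in R^d); categorical feature j ⇒ embedding row + per-feature
  bias; learned `[CLS]` prepended. Stack shape (k+1)×d.
* Blocks (×3): prenorm residual attention then prenorm residual GEGLU
  feed-forward. Multi-head attention uses 4 heads with 1/√(d/heads) scaling.
  The gated GELU is realized as GEGLU: the first projection produces value
  and gate halves of 456 units each (the stated hidden width is per branch),
  and the hidden activation is `value ⊙ GELU(gate)`. GELU itself uses the
  standard tanh approximation (exact to ~1e-3), chosen because the erf form
  is an order of magnitude slower in this environment and the difference is
  far below training noise.
* Dropout 0.1 on attention probabilities, on the feed-forward hidden
  activation, and on each residual branch; all off in evaluation mode, which
  is exactly deterministic.
* Head: final LayerNorm of the `[CLS]` position, then a plain linear map to
  one logit (no extra nonlinearity). Probability = sigmoid(logit); binary
  calls use the 0.5 probability (logit 0) cut; confidence = max(p, 1−p).

Initialization is uniform Kaiming-style fan-in for tokenizer, projections
and head; LayerNorm gains 1, biases 0; per-feature biases are separate
parameters (not shared). The forward and backward passes are hand-written on
NumPy arrays; gradients are validated against central finite differences at
float64 in the test suite. Working precision is float32 (the passes are
memory-bound); float64 is available for exact checks. Checkpoints store the
config JSON plus all parameter arrays in one archive and round-trip
bit-exactly.

## Training

Loss: binary cross-entropy with logits against label-smoothed targets,
`y' = y(1−α) + α/2` with α = 0.05 (two-class uniform smoothing, so targets
live in [α/2, 1−α/2] and the optimal logit for a pure class is the finite
ln((1−α/2)/(α/2)) ≈ 3.66). Per-row weights rescale the loss, normalized by
the **sum of weights**, so a zero-weight row contributes nothing — this makes
`pseudo_loss_weight = 0` exactly equivalent to training on the hard rows
alone under deterministic settings (no dropout, full batch), which is tested.

Optimizer: Adam with decoupled weight decay (lr 1e-4, decay 1e-5 by
default), applied to all parameters. Early stopping on validation loss with
patience (default 20, max 200 epochs), restoring the best-validation
checkpoint. One seed drives initialization, shuffling and dropout.

### Pseudo-labeling loop

* Iteration 0: supervised warm start on hard rows.
* Each subsequent iteration scores the still-unpromoted soft rows of the
  train and validation splits; rows with confidence **strictly above** 0.95
  are promoted into their own split's pool (train soft → train pool,
  validation soft → validation pool; never across splits and never the test
  split) with label 1 iff p > 0.5 and weight `pseudo_loss_weight` (default
  1.0 — equal weighting).
* Pseudo-labels are frozen once assigned; an optional rescoring mode exists
  behind a flag. Promoted validation rows contribute to the validation loss
  with their (smoothed) frozen pseudo-labels, since no other target exists
  for them.
* Retraining continues from the previous checkpoint (fine-tuning); a
  from-scratch mode exists behind a flag. The loop stops when an iteration
  promotes nothing or after 10 iterations.
* No class re-weighting is applied; the stratified split is the only
  imbalance control.

## Evaluation

`confusion_by_source` cross-tabulates the six original categories against
binary calls (all six rows always present). The 2×2 panel pools positives =
{Pathogenic, Likely Pathogenic} and negatives = {Benign auto, Benign, Likely
Benign}; VUS is excluded because it has no binary ground truth — this single
convention reproduces the full seven-metric reference panel simultaneously,
which the test suite verifies. Metrics with zero denominators return NaN
with a warning rather than a flattering 0. Logit summaries report
per-category quantiles and the fraction of logits strictly inside (−2, 2),
the low-confidence band around the decision boundary.

## Synthetic data

The generator emulates the statistical shape of a real annotated cohort at
configurable scale:

* A latent pathogenicity score z ~ N(0,1) per variant; true class = 1 iff
  z > 0.
* Informative numerical features are `signal_strength · z + ε`, ε ~ N(0,1)
  (the first one is emitted through a logistic transform as an
  allele-frequency-like column, common-when-benign, giving worst-case
  imputation hints a natural target); informative categorical features tilt
  their category log-odds linearly in z; keyword columns draw
  pathogenic-flavoured or benign-flavoured annotation strings with
  z-dependent odds. The complement of `informative_fraction` (default 0.5)
  is pure noise. An optional `correlation` knob mixes a shared factor into
  the numerical noise; no default correlation is claimed.
* Labels: category counts are one multinomial draw from the composition
  (default VUS 0.80, Likely Benign 0.11, Likely Pathogenic 0.07, Pathogenic
  0.01, Benign auto 0.006, Benign 0.004 — about 80% VUS and 2% hard, with
  the hard mass concentrated in Pathogenic as in curated archives, while
  keeping every stratum ≥ 3 rows at n = 3000). Hard labels occupy the outer
  latent quantiles, so they are class-consistent by construction; the
  likely-*/VUS assignment ranks a noise-perturbed copy of z (SD 0.5), which
  places likely labels on the matching side with genuine overlap into the
  ambiguous middle.
* Missingness is MCAR per column (default rate 0.1); an MNAR mode tilts the
  drop probability with z for studying worst-case imputation. Labels and
  identifiers are never masked.

What the generator does **not** emulate: real annotation tables have
hundreds of columns with block-correlated predictors, missingness that
follows annotation-tool coverage rather than a per-column rate, and label
errors. Passing tests on this generator therefore demonstrate that the
machinery is correct and that the training procedure recovers a planted
signal under the stated label regime — not that any particular clinical
performance level would be attained on real data.

## Problem sizes and study configuration

The recovery studies (tests and the acceptance script) run the full
procedure at n = 3000 variants with a compact table (6 numerical, 2
categorical, 1 keyword column) and a scaled-down architecture (d = 16,
2 layers, 2 heads, feed-forward width 32 per GEGLU branch), trained with
lr 3e-3, batch 256, ≤60 epochs, patience 8. These sizes are the package's choice for routine
single-CPU runs; the paper-scale defaults (d = 64, 3 layers, 456-wide
feed-forward, lr 1e-4) remain the package defaults for real use. Across five
fixed seeds the scaled-down study promotes >99% of likely-labelled rows and
keeps the held-out AUC of the semi-supervised model within 0.02 of the warm
start — both recomputed, never stored.

## Numerical choices and edge cases

* Strict inequalities are used where a boundary matters: missingness drop at
  >0.25, promotion at confidence >0.95 (a row exactly at the threshold is
  not promoted), variance drop at ≤ threshold, pathogenic call at p > 0.5
  (ties go to benign).
* Softmax is computed with max-subtraction; the BCE uses the log1p-exp
  stable form; the logistic function is branch-stable for large |logit|.
* Batched eval predictions agree across batch sizes to machine precision
  (BLAS blocking may differ at the last ulp); binary calls are batch-size
  invariant.
* Degenerate inputs fail loudly: empty training pools, all-missing columns
  reaching imputation, constant columns reaching a scaler, out-of-range
  categorical codes, overlapping positive/negative sets in the collapse.

## Known limitations

* Pure-NumPy training is single-threaded and memory-bound; the default
  architecture is practical up to tens of thousands of rows, not millions.
* The pseudo-labeling analysis offers no guarantee against confirmation
  bias: with weak signal the loop can confidently mislabel; the AUC-recovery
  test bounds degradation only under the generator's conditions.
* Validation-side early stopping during later iterations partly relies on
  pseudo-labelled rows, an inherent circularity of the procedure (the
  alternative — validating only on the ~2% hard rows — is noisier).
* The worst-case imputation directions must be supplied by configuration;
  nothing infers them from column names.
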