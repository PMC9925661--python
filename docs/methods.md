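# Methods

## Problem and model

The package estimates an eight-item depression symptom profile (PHQ-8: loss
of interest, depressed mood, sleep disturbance, fatigue, appetite change,
feelings of failure, concentration problems, psychomotor change; each item
0–3) from the transcript of a clinical interview, treating the task as
multi-target regression rather than the usual binary depressed /
non-depressed classification.  The total (0–24) is dichotomised at the
standard cutoff 10 and binned into five severity classes
([0,5) none, [5,10) mild, [10,15) moderate, [15,20) moderately severe,
[20,24] severe); a per-symptom presence cutoff of 1.5 points is used for
binarised per-symptom evaluation.

The encoder is hierarchical.  A turn encoder maps each dialogue turn to a
fixed vector by mean-pooling token representations.  Two backends are
provided: a pretrained sentence encoder (requires the optional
`sentence_transformers` dependency and raises an explicit error when it is
unavailable) and a *hashing embedder* — tokens are lowercased,
whitespace-split and mapped to fixed random vectors seeded from a stable
hash of the token — which is deterministic, dependency-free and fast, and
is the backend used in every experiment in this repository.  A single-layer
BiLSTM (default width 300 per direction; the synthetic experiments use 32)
runs over the turn embeddings, and Bahdanau-style additive attention
(`score_i = v^T tanh(W u_i + b)` over the concatenated directional states,
softmax-normalised, 128-wide projection by default) pools the states into
the interview embedding.  A feed-forward head — linear, LeakyReLU,
LayerNorm, linear — produces the output.  Four heads share this trunk:
eight symptom scores (the model of interest), and three baselines (binary
logits, five-class severity logits, a single total-score regression).
Symptom predictions are clamped to [0,3] at inference only, so training
gradients are unmodified.

The whole network, including backpropagation, is written in NumPy.  The
backward pass also returns gradients with respect to the turn embeddings;
this is exact, which makes the gradient saliency below an exact first-order
attribution rather than an automatic-differentiation byproduct.  A
finite-difference test verifies every parameter block and the input
gradient to 1e-5.

## Objectives and training protocol

The symptom head minimises the multi-target Smooth L1 loss: the mean over
the eight symptoms of `0.5 r^2` if `|r| < 1`, else `|r| - 0.5` (both
branches equal 0.5 at `|r| = 1`).  Classification baselines use softmax
cross-entropy; the total-score baseline uses a single-target Smooth L1.
Optimisation is AdamW (decoupled weight decay 0.01, applied to matrices
only) with a linear warm-up over the first 10 % of optimizer steps followed
by linear decay to zero.  A checkpoint is kept after every epoch and the
epoch with the highest binary-diagnosis micro-F1 on the development split
is returned (ties keep the earliest epoch); the same selection rule is used
for all heads, with each head's output recast to a binary label.  The
selection task is configurable: on the synthetic corpora the binary dev
task saturates within a handful of epochs, after which binary micro-F1
cannot distinguish checkpoints and returns underfit models whose
continuous predictions over-correlate the core affective symptoms; the
end-to-end recovery experiment therefore selects on 5-class severity
micro-F1 (recast from each head's output), which keeps improving as the
symptom profile sharpens.  Reported results average five training runs
under different seeds (mean ± sample standard deviation).

The default configuration (200 epochs, learning rate 3e-5) matches the
protocol for fine-tuning a large pretrained encoder.  The synthetic
experiments in the tests train small, randomly initialised models from
scratch, for which that rate is far too small; they use learning rate 3e-3,
batch size 4, and 30–50 epochs.  These are reduced-scale study conditions,
chosen once: 40-interview corpora for loss-decrease and unit checks, and a
560-interview corpus (400 train / 60 dev / 100 test) with a
48-dimensional embedder and width-32 BiLSTM for the end-to-end recovery
experiment.

## Evaluation

Regression: MAE, and macro-averaged MAE where the MAE is computed inside
each of the five severity classes of the gold totals and the occupied
classes averaged with equal weight (empty classes on small splits are
skipped and logged — the alternative of counting them as zero would reward
absent bins).  Classification: micro-F1 (true/false positive/negative
counts pooled over classes; equal to accuracy for single-label problems)
and macro-F1 (unweighted mean of per-class F1, a per-class F1 with zero
denominator defined as 0).  Per-symptom: MAE; RRMSE — RMSE normalised by
the RMSE of predicting the training-split mean of that symptom, so 1.0
means "no better than the mean predictor" and the statistic is undefined
when the gold column is constant at that mean; and presence/absence F1 at
the 1.5 cutoff.  Severity-group mean profiles (mean gold and predicted
profile per severity class and per binary group) support radar-style
plots.  All metric implementations are tested against independent
brute-force loop oracles at 1e-10 or tighter.

## Symptom networks and the comparison test

Symptom networks are estimated from score tables (rows = participants,
columns = the eight symptoms).  The correlation graph uses Spearman by
default (the scores are ordinal; Pearson is available).  The regularized
network is an L1-penalised inverse-covariance (graphical lasso) fit: a
100-point logarithmic penalty path from the largest absolute off-diagonal
correlation down to 1 % of it, the Extended Bayesian Information Criterion
with gamma = 0.5 selecting the penalty (ties resolved toward the sparser
fit), and the selected precision matrix standardised into partial
correlations.  The diagonal is left unpenalised, the convention of the
psychological-network literature.  The coordinate-descent solver is
numba-compiled and warm-started along the path; it is validated against a
library graphical-lasso implementation across penalties (5e-5) and against
closed-form matrix-inversion partial correlations at zero penalty (1e-6).
The speed matters: the permutation test below re-estimates two networks
per permutation, and calibration studies run hundreds of tests.

The Network Comparison Test compares two groups: M is the largest absolute
edge-weight difference (invariant structure) and S the absolute difference
of the summed absolute edge weights, each unordered pair counted once
(invariant global strength).  The null distribution pools the rows,
re-splits them at random into groups of the original sizes and
re-estimates both networks; p-values use add-one smoothing,
`p = (1 + #{perm >= obs}) / (1 + n_perm)`, so they are never zero.
Default 1000 permutations; simulation studies in the tests use 250
permutations and a 10-point penalty path to keep hundreds of repetitions
tractable.  At group size 60 under the default generator the EBIC networks
are often empty, which concentrates null p-values at 1 (the test stays
conservative and the type-I rate is controlled); the p-value-uniformity
check therefore uses groups of 100, where the networks are dense enough
for the statistic to be effectively continuous.

## Synthetic corpus generator

Because the clinical corpus is access-restricted, all experiments run on a
generator that reproduces the structure the method relies on:

* **Scores.** A Gaussian copula: a latent 8-variate normal with a
  single-factor correlation matrix (loadings 0.80, 0.85, 0.65, 0.70, 0.60,
  0.75, 0.65, 0.50 — affective core items highest, the psychomotor item
  lowest) discretised through per-symptom thresholds.  Core thresholds
  (−0.10, 0.75, 1.60) give marginal P(score 0) ≈ 0.5 and P(score 3) ≈ 0.05;
  the psychomotor item uses (0.50, 1.25, 2.00), shifting it toward low
  scores the way that symptom is rarely verbalised.  The realized depressed
  rate (total ≥ 10) is ≈ 24 %, matching the class imbalance of the
  reference corpus, with the configured target rate 0.30 checked to within
  ±10 points.
* **Dialogues.** 4–6 opening small-talk turns; a middle block with one
  question/answer pair per symptom where the answer contains exactly as
  many symptom-marker utterances as the gold score (score 0: a neutral
  line half the time), drawn from a template bank with ≥4 variants per
  symptom per intensity tier; the prompt "have you been diagnosed with
  depression" whose answer is congruent with the true binary status with
  probability `leakage` (default 0.8) and otherwise incongruent or evasive
  with equal odds; and ≥2 closing turns.
* **Splits.** Disjoint train/dev/test with per-split label distributions
  logged.

What the generator does *not* emulate: linguistic variety beyond the
template bank, figurative symptom expression, disfluencies, annotation
noise, or any audio/visual channel.  Passing tests on this corpus
demonstrate that the pipeline recovers a learnable symptom signal with the
right statistical structure — not clinical-grade performance on real
interviews.

## Interpretability analyses

Turn saliency for symptom k is the L2 norm (absolute sum available) of the
gradient of the unclamped predicted score with respect to each turn's
embedding — the turn is the input feature, so the gradient is taken at the
turn level, not the token level.  Answers to the diagnosis question are
classified yes/no/other by a cue-lexicon scan with a 3-token negation
look-back window; the lexicon is a reconstruction shipped as editable YAML.
Association between answers and diagnostic groups uses the two-sided
Fisher exact test on the 2×2 table with "other" excluded.  The robustness
check swaps every yes answer for a random no variation and vice versa,
resamples "other" answers, leaves every remaining turn byte-identical, and
reports signed metric deltas before/after.

## Numerical choices and degenerate inputs

Attention scores are softmax-stabilised by max subtraction; LayerNorm uses
eps 1e-5; sigmoid inputs are clipped at ±60; empty turns map to the zero
embedding.  Zero-variance score columns get zero edges with a warning.
Fisher tables with an empty row or column, constant gold equal to the
training mean (RRMSE), non-positive-definite correlation matrices, and
splits too small to be nonempty all raise explicit validation errors.
Checkpoint-selection ties keep the earliest epoch; EBIC ties keep the
sparser fit.

## Known limitations

The NumPy model is CPU-bound and intended for the bundled synthetic scale,
not for fine-tuning pretrained encoders.  The permutation comparison of a
*predicted* network against the *gold* network of the same participants
treats paired tables as independent groups — the same design as the
analysis it follows — which makes its p-values approximate.  The
answer-classification lexicon is a small rule set and will misread answers
outside its cue vocabulary.
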