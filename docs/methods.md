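# Methods

`cnnsad` implements a staging-assisted diagnosis model for non-small-cell
lung cancer (NSCLC): free-text clinical records are classified into clinical
stages I-IV by a convolutional text classifier trained one-vs-rest, with a
dynamic-sampling loop to handle heavy stage imbalance and a label
co-occurrence transfer scheme to warm-start small-sample stages. This note
documents the model, the synthetic data that stands in for the (private)
hospital cohort, the numerical choices, and what the tests do and do not
show.

## Model

**Text encoding.** Records are token sequences. Skip-Gram embeddings of
dimension k are pretrained on the corpus: each center token predicts the
tokens in a window of radius n by maximizing the summed log probability of
the context set, with the context softmax approximated by negative sampling
(exact softmax is quadratic in vocabulary size; the estimator is otherwise
unconstrained, and 5 negatives is the conventional choice). A record becomes
the n_tokens x k matrix of its token vectors in order; out-of-vocabulary
tokens map to a shared UNK vector trained as an ordinary token, and records
are padded with all-zero PAD rows / truncated to a fixed length.

**Classifier.** Convolution kernels of window sizes {2, 3, 4} slide over the
record matrix; kernel c with bias a emits f(<c, X_{i:i+m-1}> + a) per
position with f = ReLU. Each feature map is max-pooled to one activation, so
the feature vector's length equals the kernel count, and a fully connected
softmax layer produces class posteriors. Window sizes and kernel counts are
free choices (32 per window at full scale, 8 per window in the test-scale
architecture used throughout the test suite and the reproduction script,
which keeps a 10-fold cross-validation of the full procedure within minutes
on one CPU).

**Diagnostic value F(x).** Clinical practice for this model reports a
scalar severity score whose calibrated per-stage ranges are I: 18-57,
II: 58-119, III: 119-180, IV: > 180. No closed form ties the score to the
classifier's output, so F(x) is defined here as the posterior-weighted mean
of per-stage anchor values — the range midpoints 37.5, 88.5, 149.5, and 240
(stage IV's range is open above 180; 240 is a declared constant). The
inverse map `stage_from_score` uses half-open intervals (18, 57], (57, 119],
(119, 180], (180, inf), assigning boundary values to the lower stage (the
printed ranges are ambiguous at 119); scores at or below 18 return
"indeterminate". By construction each stage's anchor maps back to its own
stage, so one-hot posteriors round-trip.

**One-vs-rest staging.** Each stage gets a binary head (2-class softmax, so
the positive-class posterior is directly the P used by the sampler). The
ensemble prediction renormalizes the four positive posteriors into a
four-class posterior; the stage is its argmax and F(x) follows from the
anchors.

## Dynamic sampling

For a target label with N_pos positives and N_neg negatives, per-record
sampling probabilities start per-class uniform at size/(2 N_pos) and
size/(2 N_neg), so each class sums to size/2 (block size `size` = 64 by
default; accuracy peaks there in the source study's block-size sweep). Each
iteration: draw a block (each record included independently with
probability rho), take one shuffled SGD pass over the block, score the full
training corpus, multiply positives' rho by exp(1 - P) and negatives' by
exp(P), and renormalize each class back to size/2. Misclassified and
low-confidence records therefore gain sampling mass while drawn blocks stay
balanced — the conservation invariant is asserted to 1e-9 every iteration in
the tests.

When a class is smaller than size/2, its probabilities exceed 1; a record
with rho > 1 contributes floor(rho) deterministic copies plus one more with
probability rho - floor(rho). This keeps the expected copy count equal to
rho, which strict Bernoulli inclusion cannot, and so preserves the balance
law. The loop runs a fixed iteration count (no convergence heuristic), with
one gradient epoch per drawn block by default; both are configurable.

## Transfer learning

Label co-occurrence T(a, b) counts records whose label set contains both
labels; the table is symmetric and its diagonal counts each label's support.
A small-sample stage's head is initialized from the head trained on the
label it co-occurs with most (stages never co-occur with each other — every
record carries exactly one stage — so in practice the source is an auxiliary
finding label). Ties break by larger support, then lexically; a target that
co-occurs with nothing falls back to the largest-support label. All
parameters are deep-copied and all layers fine-tune (no freezing by
default); the source is never mutated.

## Synthetic records

The real 8,920-patient multi-hospital cohort is not public. The generator
emulates the statistics the method depends on:

* **Stage imbalance.** Default stage weights 752 : 1497 : 3926 : 2745
  (stages I-IV), the cohort's split; stages are drawn per record, so counts
  are multinomial.
* **Tumor markers** (CYFRA21-1, CEA, CA125, SCC, CA19-9, CA15-3, ng/ml):
  truncated-normal at 0, stage-conditional means on a linear severity ramp
  mean_s = (s/3) x stage-III mean. Stage III is the modal stage (weighted
  mean stage index 2.97), so the cohort-wide means land on the clinically
  reported patient averages — CYFRA21-1 about 35, CEA about 80 (16x the
  upper normal bound), CA125 about 175 — while stage IV is most elevated.
  SCC/CA19-9/CA15-3 patient averages are not reported anywhere; their
  stand-in stage-III means are 4x the upper normal bound. Noise sd is 25%
  of the stage-III mean per marker. Healthy controls draw uniformly inside
  the normal ranges (CYFRA21-1 0-1.80, CEA 0-5, CA125 0-35, SCC 0-1.5,
  CA19-9 0-37, CA15-3 0-30).
* **Text channel.** The classifier sees only tokens, so the diagnostic
  signal is verbalized: body tokens mix a shared clinical vocabulary with a
  stage-specific sub-vocabulary (fraction `stage_signal_strength`, default
  0.3 — most clinical text is shared boilerplate), and each marker
  contributes its name token plus an elevation-bin token (multiples of the
  upper normal bound: <1x, 1-2x, 2-4x, 4-8x, >8x), a graded severity signal.
* **Label structure.** Besides the stage label, records may carry `smoker`
  (prevalence rising with stage, 0.35 to 0.65) and severe-elevation flags
  `CEA_elevated` / `CA125_elevated`. The flag thresholds sit at the
  cohort-average patient levels (CEA 80, CA125 175), not at the upper
  normal bounds: cancer elevates these markers in essentially every
  patient, so normal-bound flags would be universal and the co-occurrence
  table would carry no information; the chosen thresholds split the corpus
  roughly in half and correlate with stage, giving the transfer step a
  meaningful source task.

All randomness flows from one seed through `numpy` `SeedSequence` spawning,
one sub-stream per record: corpora are byte-identical across runs and
records are exchangeable.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic clinical language (tokens are abstract
symbols), inter-marker correlation within a patient, label noise or
incorrect staging, records whose text contradicts their markers, and
distribution shift between hospitals. Because stage-specific tokens are
(noisily) present in most records, the synthetic task is close to separable;
cross-validated accuracies near 1.0 here say the pipeline works end to end,
not that real staging is this easy.

## Numerical choices

* **CNN training** is plain minibatch SGD on cross-entropy with
  hand-derived gradients, verified against central differences to 1e-4
  relative error. Gradients flow through each kernel's max-pooled window
  only (subgradient of max, ties to the first position) and through the
  ReLU mask. No optimizer state keeps determinism trivial: identical seeds
  give bit-identical parameters.
* **Skip-Gram** uses batched SGD (batch 512) with scores clipped to +-6 and
  a linear learning-rate decay from the initial rate to near zero across
  training — without both, tokens that occur in every record (marker names)
  accumulate many same-direction updates inside one batch and oscillate.
  Context vectors initialize uniformly at random rather than zero; zero
  initialization imprints a shared drift direction on every vector early in
  training. PAD is pinned to the zero vector and never trained.
* **Padding** rows are zero vectors; they are excluded from max-pooling only
  implicitly (a window of zeros contributes f(bias), constant across
  records).
* **Accuracy** defaults to (TP+TN)/total. An alternative mode
  `"as-printed"` computes (TP+FN)/total, a variant that appears in some
  write-ups of these formulas; it is preserved behind a flag and never used
  by default. Undefined metrics (zero denominators) are reported as NaN
  with a warning, never as 0.
* **Cross-validation** is stratified k-fold (k=10 by default), macro-
  averaging one-vs-rest metrics over the four stages within folds and then
  over folds; k = n degenerates to leave-one-out. Embeddings are pretrained
  once per corpus rather than per fold — the objective is unsupervised, so
  no label information leaks into folds.
* **Sampler edge cases:** probabilities are validated finite and
  non-negative after every update; a non-finite state aborts with a dump of
  the class sums. Whether a uniform draw "< rho" or "<= rho" admits a
  record is measure-zero; `<` is implemented.

## Study sizes used by the reproduction script

`scripts/acceptance.py` generates 3,000-record corpora at the default stage
proportions, pretrains k=8 window-2 embeddings, trains the four one-vs-rest
heads with the dynamic-sampling loop (size 64, 30 iterations) inside
stratified 10-fold cross-validation, and averages macro accuracy over three
corpus seeds. These sizes match the sample-size/accuracy claim under test
(accuracy above 80% once training reaches 3,000 records) at the test-scale
architecture.

## Known limitations

* F(x) is a declared surrogate; its anchors are calibrated to the printed
  stage ranges but carry no independent clinical meaning.
* The transfer source is always a single label; multi-source transfer and
  freezing schedules are out of scope (freezing exists as a config option).
* The sampler scores the entire training corpus every iteration; cost is
  linear in corpus size per iteration and this is the dominant training
  cost at scale.
* Embedding quality at k=8 on small synthetic corpora is dominated by a
  shared similarity component; the classifier compensates, but nearest-
  neighbor structure in the embedding space should not be over-interpreted.
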