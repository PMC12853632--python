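# Methods

This note documents the modeling and numerical choices behind `herbrec`:
what each stage assumes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Data model and co-occurrence

A clinical record is a set of symptom terms and a set of herb terms with a
domain tag (`source` = the stomach/spleen-style corpus, `target` = the
lung-style corpus).  Duplicate terms within a record are collapsed; counting
is per-patient binary, so `C_ij ≤ n_records` always.  Vocabularies are
union vocabularies with per-domain membership; ordering is first-occurrence
by default (deterministic for a fixed file) with a lexicographic option that
is invariant to record permutation.

**Sample-level sparsity** is defined as `1 − (mean set size per record) /
(vocabulary size)`.  The denominator is the vocabulary of the corpus being
measured by default, with the union vocabulary behind a flag: the published
per-corpus sparsity figures are consistent with the per-corpus reading for
the herb axis (1 − 20.98/928 = 97.74%), and no single denominator reproduces
every published figure, so both conventions are exposed.

**Train/test split**: seeded uniform shuffle, train size `floor(0.8·N)`.
This floor convention reproduces both published split-count pairs
(14,948 → 11,958/2,990 and 17,593 → 14,074/3,519).

## Autoencoders over co-occurrence profiles

Each entity's profile (herb row / symptom column of the per-domain count
matrix, zero-padded to the wider domain) is reconstructed through one
hidden layer with ReLU on both layers.  The loss is the square error summed
over *observed* positions only — positions with a nonzero count, the
implicit-feedback AutoRec convention, since the data never distinguishes
"observed zero" from "unobserved" — plus an L2 penalty `α` on all weights
and biases (default `α = 1e-3`; an optional `log1p` transform of counts is
off by default).

Initialization uses fan-in-scaled uniform weights taken in absolute value,
with biases at 0.1.  The absolute value matters: profiles and targets are
nonnegative, and with ReLU on both layers a sign-symmetric initialization
routinely drives the whole encoder into the dead region (latent identically
zero, decoder bias fitting column means) — a fixed point gradient descent
cannot leave.  With the nonnegative initialization the same optimizer
recovers a planted rank-1 matrix to ~1e-5 relative error.

Training is full-batch Adam (default lr 1e-3), early-stopped after 20
epochs without improvement, returning the best parameters seen, so the
final loss never exceeds the initial loss.

## Domain-adversarial refinement

The refinement stage is a feature extractor, a rating predictor and a
domain classifier (each a fully connected ReLU stack, 2 hidden layers of 64
units by default).  The single objective is

    L(θ_f, θ_r, θ_c) = loss_pred(θ_f, θ_r) − μ·loss_domain(θ_c) + λ‖θ‖²,

with `loss_pred` the squared reconstruction error of the rating vectors
(by default the original padded profiles when run through the pipeline) and
`loss_domain` the binary cross-entropy of the classifier.  The minus sign
is realized with gradient reversal inside a single optimizer rather than an
alternating min–max, matching the single-objective form; `cpm_loss` reports
the summed objective exactly as written.

Two numerical choices depart from the naive transcription, both forced by
optimization behavior observed on controlled fixtures:

* **Confusion-form reversal.**  The raw reversed cross-entropy gradient
  vanishes once the classifier saturates (its sigmoid outputs hit 0/1), at
  which point the extractor receives no adversarial pressure; on shifted
  Gaussian fixtures the classifier stayed at accuracy 1.0 indefinitely.
  The reversed signal therefore uses the gradient of the cross-entropy
  toward a uniform 0.5 target, which is nonvanishing everywhere.  With it,
  both the co-trained classifier and an independently trained logistic
  probe drop to chance on the same fixtures.
* **Standardized inputs, mean-scaled terms.**  Latent features can have
  large scale (std ≈ 10 on count profiles), which makes the summed
  reconstruction gradient swamp the bounded domain gradient.  Inputs and
  targets are z-scored over the pooled domains, and both loss terms enter
  the gradient mean-scaled, so `μ` has a scale-free meaning (default 1).

Early stopping monitors the rating loss only (the one bounded-below term)
and keeps the final parameters: restoring an earlier best-reconstruction
state would undo adversarial progress.

Per-domain refined vectors are merged over the union vocabulary: a term
present in one domain keeps its vector, a shared term gets the elementwise
mean (keeps the dimension fixed and is symmetric in the domains);
concatenation is available behind a flag.

## Recommender

The patient branch mean-pools the active symptom rows of `E_s` and applies
a 7-layer MLP; the herb branch applies a 5-layer MLP to every row of `E_h`;
both end at a shared width (default 128) so the dot product in
`sigmoid(Z_p · Z_hᵀ)` is defined.  Hidden layers are ReLU; **the final
layer of each branch is linear by default**.  Ending both branches in ReLU
would make every dot product nonnegative, flooring all probabilities at
0.5; worse, for any herb prescribed in fewer than half the records the
cross-entropy optimum is then the dead-network state, and training
measurably collapses to loss ln 2 with degrading rankings.  The ReLU-ended
variant remains available (`final_relu=True`) for comparison.

Training: BCE against the patient's full herb multi-hot (no negative
sampling), averaged over herbs and batch; Adam lr 1e-3; L2 weight decay
λ = 1e-3; dropout 0 by default (enabling it consistently hurt in the tuned
configuration this package mirrors); early stopping with patience 20,
restoring the best epoch.  Embedding tables stay frozen during recommender
training.  Unknown symptoms at inference are dropped with a warning
(clinical free text is open-vocabulary); a patient whose every symptom is
unknown is an error.  Checkpoints are single JSON files carrying parameter
arrays, config and vocabulary hashes, and refuse to load against a
mismatched vocabulary.

## Evaluation

Top@K metrics are micro-averaged: numerators and denominators pooled over
samples before division, F1 computed from the pooled P and R.  Predicted
lists shorter than K are legal (the precision denominator uses actual list
sizes); an empty truth set is an error since its recall contribution is
undefined.

## Network-pharmacology proximity

Distances are unweighted BFS shortest paths.  `S_AB` uses the
closest-distance convention: within-set means exclude the node itself
(singleton sets contribute 0), the cross term averages, over every node of
both sets, its distance to the nearest node of the opposite set (shared
nodes contribute 0).  The z-score compares observed `d_AB` against
`n_rand` (default 10,000) uniformly random node-set pairs of the same
sizes; a degree-binned sampler is available behind a flag since
network-medicine practice often degree-matches, but the uniform null is the
default.  ASPL is the plain mean over all cross-set pairs, which always
dominates the closest-distance mean.  The edge permutation test counts
edges with one endpoint in each set, estimates the per-pair rate from the
permutation null mean (default 1,000 rounds), and reports the upper-tail
binomial probability of the observed count among `|A|·|B|` pairs.
Unreachable nodes/pairs are dropped from means with a warning by default;
strict mode raises.

## Synthetic data

The generator draws per-record set sizes from a truncated Poisson (minimum
1) around corpus-specific means, terms from a Zipf-like law (exponent 1.1,
rank order seeded) giving the long-tailed frequency profile real corpora
show, and plants a symptom→herb rule table: a trigger symptom implies its
paired herb with probability `rule_strength` (default 0.8), with rules on
shared terms identical in both domains — the minimal structure under which
cross-domain transfer can help — and extra domain-specific rules elsewhere.
A noise rate (default 0.05) resamples non-rule herb slots.  After drawing,
any vocabulary term that failed to appear is injected into one record of
its domain, so generated vocabulary overlaps match the spec exactly.

The full-size preset mirrors the published corpus profile (record counts,
mean set sizes 13.58/17.39 symptoms and 20.98/7.89 herbs, 285 shared herbs,
328 shared symptoms); the per-domain vocabulary sizes, which were not
published, are chosen to reproduce the published union sizes (928 herbs,
42,975 symptoms).  A `scale` parameter shrinks records, vocabularies and
overlaps together.

What the generator does **not** emulate: real symptom text and its
synonymy/normalization problems, herb dosage, inter-herb compatibility
structure, physician-specific prescribing styles, and any genuine
biological link between the corpus and the PPI fixtures.  Passing tests on
this data therefore demonstrate that the pipeline recovers plantable
co-occurrence structure and that its statistics are correctly computed and
calibrated — not clinical-grade recommendation quality.

The PPI generator plants two disjoint node sets in an Erdős–Rényi graph and
resamples every cross-pair edge at `boost × edge_prob`; `boost = 1` leaves
the planted pair exactly background-distributed, which is what makes the
null-calibration check meaningful.

## Problem sizes used in the checks

The framework-level checks run at 200 records per domain with embedding
dimension 32 and branch output width 64; the calibration/power checks use
150-node graphs with edge probability 0.05, set size 10 and 200 permutation
rounds over 50 seeds.  These sizes were chosen so every behavior of
interest (planted-rule recovery, domain confusion, null calibration,
power) is comfortably detectable while the whole suite stays interactive.

## Known limitations

* All networks are trained with a hand-written numpy backprop core —
  adequate for the model sizes here, not for GPU-scale corpora.
* The adversarial stage balances reconstruction against domain confusion;
  with self-reconstruction targets a perfectly domain-invariant extractor
  is unreachable in principle, and `μ` controls the trade-off.
* The binomial p-value treats inter-set pairs as independent, which ignores
  shared-endpoint correlation between edges; the permutation null it is
  calibrated against carries the same structure, and the null-calibration
  check shows the combination is conservative rather than anti-conservative.
* Herb dosage, compatibility rules and treatment-principle reasoning are
  out of scope.
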