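# Methods

This note records the models implemented, the numerical and design
choices made where the procedure was genuinely open, what the synthetic
generators emulate, and the known limitations.

## Task and data model

An instance is one tokenised sentence with two non-overlapping entity
spans and a binary label: +1 (the entities stand in a semantic relation)
or −1. Spans are 0-based half-open `[start, end)` everywhere; external
inclusive index conventions are converted at the boundary (`end =
inclusive_end + 1`). Precision, recall and F1 take +1 as the positive
class, with zero-denominator cases defined as 0 so that threshold sweeps
are total.

## Dependency detector (SARD)

The detector extracts the shortest dependency path (SDP) between the two
entity tokens in the undirected dependency tree (unique because the
structure is a tree; `networkx` finds it, and tests cross-check against
an independent BFS). Three nested assumptions gate the prediction — the
root is a verb and on the SDP; the root is on the SDP; any verb is on
the SDP — combined with a direct-link escape (an SDP of exactly two
nodes) and, under heuristic 2, a veto when a conjunction tag appears on
the path.

Open points and the defaults chosen:

* **Entity anchoring.** Multi-token entities are represented by their
  syntactic head: the leftmost span token whose own head lies outside
  the span. This is the standard SDP endpoint choice.
* **Conjunction tag set** = {CCONJ, SCONJ}: coordinators are the
  motivating case ("and", "but"); subordinators also split clauses.
  Configurable.
* **Verb test** uses UPOS `VERB` only; auxiliaries are excluded (an
  auxiliary chain without a main verb rarely expresses a relation).
  Configurable.
* **Entity tokens count as path nodes** for the conjunction veto — the
  rule is stated over the whole path without exclusions.

Parses come from CoNLL-U files or any parser adapter; the core never
invokes a parser, so all tests are parser-free.

## Attention detectors

For one encoder layer, `A` is the head-averaged self-attention matrix
(row-stochastic by construction). Entity attention vectors are means of
the entity's subtoken rows; the localized context distribution is their
normalized Hadamard product `L = (a₁ ∘ a₂)/(a₁·a₂)`, a probability
vector over positions. PicMI thresholds `max L`; PicMI-Up thresholds the
entities' mean attention to `argmax L` (ties → lowest index,
deterministic); ConEx thresholds `KL(L ‖ U) = ln n − H(L)` in nats.
All three predict +1 when the score is ≥ the threshold, which makes the
predicted-positive set non-increasing in the threshold and recall
monotone over a sweep.

Numerical choices:

* **KL direction** is `KL(L ‖ U)`: it is finite for sparse `L` (zeros
  allowed, `0·ln 0 := 0`), whereas the reverse direction diverges on any
  zero entry; natural log matches the ConEx threshold scale
  [0.05, 0.14] at realistic sentence lengths.
* **Zero-overlap degeneracy** (`a₁·a₂ = 0`): `L` is undefined; we fall
  back to uniform with a warning and a `degenerate` flag. Zero shared
  attention means no relational signal, and uniform makes every
  detector answer −1 at any positive threshold.
* `n` is the number of subtokens handed over by the encoder adapter;
  whether special boundary tokens are included is the adapter's
  documented choice (the bundled synthetic encoder excludes them).
* Head averaging happens in the adapter; the core consumes only the
  row-stochastic matrix, so the algorithms are tested on fixtures
  without any model download. The bundled `TinyRandomEncoder` is a
  synthetic fixture (seeded random weights, no linguistic knowledge)
  that exercises the adapter contract end to end.

## Pairwise-comparison weak supervision

The labeler accepts an ordered pair (s, s′) with labels (y, y′) unless
(y, y′) = (−1, +1); invalid pairs are rejected and resampled, never
swapped (swapping would change the meaning of the acceptance rate and
break prior estimation from it). Sampling is uniform with replacement; a
draw budget (default `100·n_pairs + 10,000`) guards corpora that admit
too few valid pairs. Silver labels are computed once per instance and
cached, so detector determinism carries into SoDaG; a silver labeler
that happens to equal gold reproduces GoDaG byte-for-byte at the same
seed.

With i.i.d. labels at prior π₊ the acceptance probability is
π̃ = π₊² + π₋ (minimum 0.75 at π₊ = 0.5), invertible for π₊ given which
class dominates. The pointwise split (first elements → D̃₊, second →
D̃₋) yields known mixtures of the clean class-conditionals; the
contamination rates ρ₊ = π₋²/(π₋² + π₊) and ρ₋ = π₊²/(π₊² + π₋) drive
the noisy-label methods. Downstream training takes π₊ as a supplied
experimental control (the grid {0.3, 0.4, 0.5, 0.6}); the
acceptance-rate estimator exists but is not wired into defaults.

## Risk estimators and training

All estimators use the logistic loss `ℓ(z, y) = ln(1 + e^{−yz})`,
computed as a softplus with the overflow-safe `max(m,0) + log1p(e^{−|m|})`
form. Gradients are analytic (`dℓ/dz = −y σ(−yz)`), so training needs no
autodiff: the trainable surface is a linear head over frozen features
(precomputed pair representations or synthetic feature vectors), which
is exactly the frozen-encoder regime.

* **Pcomp-Unbiased** implements the unbiased pairwise risk; it can go
  negative, which is the overfitting mechanism the corrected variants
  address. **Pcomp-ReLU/ABS** apply g ∈ {max(0,·), |·|} to the two
  per-batch bracket means (subgradient at 0: 0 for ReLU, +1 for abs).
  g = identity recovers the unbiased form exactly — an algebraic
  rearrangement, asserted to 1e-12 in tests.
* **Binary-Biased** and **Noisy-Unbiased** are pooled means over both
  sets (the pooled mean is the reading under which the biased baseline
  equals the supervised risk on clean sets). The Natarajan-style
  surrogate uses the mixture contamination rates above; with those
  (inverse) rates the pooled corrected risk is unbiased for the clean
  risk exactly at π₊ = 0.5, where the rates are symmetric. At strongly
  imbalanced priors the correction is mis-calibrated and can degenerate
  (see `examples/train_from_comparisons.py`, which shows this openly);
  consistency checks are therefore run at the balanced prior.
* **RankPruning** fits a preliminary binary scorer, prunes the ρ₊
  fraction of D̃₊ with the lowest scores and the ρ₋ fraction of D̃₋ with
  the highest, and refits; fractions come from the mixtures rather than
  estimation, matching the controlled-π₊ protocol (an override hook
  exists).
* **Pcomp-Teacher** adds mean-teacher consistency to the pruned refit: a
  parameter copy tracks the student as an exponential moving average
  after every optimizer step, and the loss adds
  λ·mean[(f_s(x+ε) − f_t(x+ε))²] over Gaussian input perturbations.
  EMA decay 0.99, λ = 1.0, perturbation σ = 0.1 are package defaults —
  the reference procedure leaves them open.

Protocol: Adam (lr 10⁻³, β = 0.9/0.999), mini-batches of 256 pairs with
the (sᵢ, s′ᵢ) alignment preserved inside a batch, 50 epochs, dropout
0.3 where the scorer uses it, a 15% development split, best epoch by
development F1 against the noisy labels (the metric was open; F1 is the
default and configurable). Zero-epoch runs return the initialization
snapshot with empty history. Identical configs and seeds reproduce
histories exactly. The pair classifier head (average-pooled entity
embeddings → concatenation → batch normalization → inverted dropout →
affine score) applies batch normalization to the concatenated
representation before dropout; the position is configurable because the
stated pipeline fixes only "after embedding extraction". Prediction is
sign(score) with 0 → +1.

## Synthetic generators

All generators are pure functions of (config, seed).

* **Parse corpora**: five structural flags (root on SDP, root is verb,
  non-root verb on SDP, direct link, conjunction on SDP) are sampled per
  label from configurable conditional probabilities and realized by
  constructive tree templates, so the detector's expected confusion
  matrix is computable in closed form. One flag combination (all five
  true) is structurally unrealizable — a two-node path cannot host a
  verb root, a second verb and a conjunction — and is resolved by
  clearing the redundant non-root-verb flag, which leaves every derived
  predicate unchanged; the builder raises on it when called directly.
  Default conditional probabilities make related pairs verb-connected
  and unrelated pairs conjunction-heavy, a caricature of the regularity
  the SDP assumptions exploit.
* **Attention corpora**: related pairs place κ of each entity row's mass
  on a shared trigger token (with probability `peak_prob_pos`; unrelated
  pairs peak with `peak_prob_neg`, default 0), backgrounds are symmetric
  Dirichlet with concentration 200 (near-uniform; an exact-uniform mode
  exists for null tests). Setting the peak probabilities to 0.75/0.25
  at a balanced prior pins the ConEx silver-label F1 at ≈ 0.75 by
  construction, which is how the fully unsupervised pipeline is
  stress-tested with a deliberately imperfect labeler.
* **Feature corpora**: two spherical Gaussians with configurable means,
  shared σ and prior; the Bayes accuracy is reported in closed form
  (Φ(Δ/2) at a balanced prior, with the log-prior-ratio shift
  otherwise). The default 4σ separation gives Bayes accuracy 0.9772.

What passing on these corpora does *not* show: the generators have no
real token distributions, no parser or encoder errors, no entity-type
structure, and conditionally independent structural flags. Results on
them validate the algorithms and estimators, not performance on real
biomedical corpora, which additionally needs a real parser/encoder
through the adapter interfaces.

## Problem sizes

The test suite and the acceptance script run the statistical checks at
the sizes where their error bands are meaningful but cheap: 50,000
drawn/accepted pairs for the acceptance and mixture laws (3·SE bands),
100,000 mixture samples for estimator-consistency gaps (< 0.01), 60/30/12
replicates over n ∈ {10³, 10⁴, 10⁵} for the √n decay slope, 2,000
training pairs and 5 seeds for the end-to-end recoveries.

## Known limitations

* No real encoder or parser is bundled; the adapters are the seam.
* Noisy-Unbiased with mixture rates is reliable only near balanced
  priors (above).
* `estimate_prior_from_acceptance` is undefined below the theoretical
  floor 0.75 and raises there; sampling noise can push an empirical rate
  slightly below it on small corpora.
* The trainable model is a linear head; the frozen-encoder contract
  makes that the intended regime, and nonlinear heads would need their
  own gradient implementations behind the same factory seam.
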