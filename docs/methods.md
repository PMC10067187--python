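# Methods

This note records the model, the defaults and the numerical choices behind
`mdgraph`, including the places where the design was genuinely open and the
package had to commit to one reading.

## Graph model

Samples are nodes; the graph is unweighted and undirected.  Construction is
a sequential, deterministic walk: nodes are processed in index order, each
walks its distance-sorted candidate list (ties broken by ascending node
index; self excluded, since its zero distance would always qualify) and
initiates an edge whenever the candidate lies within the distance threshold
*t* and the node's initiated count is still below its cap.  Three choices
deserve comment:

- **Cap semantics.** The cap is enforced strictly (`count < τ`), so τ is
  literally the maximum number of initiated neighbors.  An inclusive
  comparison would admit τ+1 edges, contradicting τ's definition as the
  neighbor maximum.
- **Walk accounting.** A node's walk increments its initiated count for
  every accepted candidate *even when the edge already exists* from an
  earlier node's walk.  This makes "initiated degree" mean "neighbors this
  node chose", independently of insertion order, and it is the reading
  under which the construction example traces (a node whose nearest
  neighbor already linked to it ends with initiated degree 1, not 0).
  Total degree may exceed τ because other nodes initiate edges too.
- **Class-aware caps.** In the imbalanced regime the *initiating* node's
  own label selects τ_sick or τ_healthy; no constraint is placed on the
  neighbor's label.  By default the labels of all nodes — including
  validation/test nodes — shape the caps, which is what a transductive
  construction implies; `blind_caps=True` substitutes the single balanced τ
  for a label-free (leakage-free) construction.

**Thresholds.** *t* starts at the median of the N(N−1)/2 *off-diagonal*
distances; including the structurally-zero diagonal would bias *t* low.
Refinement targets every node whose initiated degree is below its cap
("sparse" in the strict sense; a `min_degree` override relaxes the target,
e.g. `min_degree=1` rescues only standalone nodes).  The raised *t* is
shared across rescued nodes and increments at most 5 times by
δ = (max − m)/5; on the fifth increment *t* is clamped to the matrix
maximum to absorb floating-point shortfall of `m + 5δ`.  Whether *t* should
reset between rescued nodes is not specified anywhere; the shared-t choice
is monotone and cheaper, and it is what the construction oracle in the test
suite encodes as well.  Caps larger than N−1 are rejected before any
mutation.

**Cosine degeneracy.** The cosine of a zero-norm abundance vector is
undefined.  The package defines its dissimilarity as 1 against any non-zero
vector (maximal ignorance) and 0 against another all-zero vector
(indistinguishable samples).

## GraphSAGE base learner

Implemented in numpy with hand-derived gradients (K concatenating mean-
aggregator layers, L2 normalisation after each layer, linear+softmax head,
Adam).  Defaults — K = 2 layers, 32 hidden units per layer (the layer
*output* width; the linear map consumes the 2×-wide concatenation),
S = (10, 5) neighbor samples, ReLU, 50 epochs, learning rate 5·10⁻³,
categorical cross-entropy — are the settings selected empirically for the
disease-graph task.  Further choices:

- **Sampling.** Without replacement when degree ≥ S_k (no duplicate bias),
  with replacement otherwise (fixed-size multiset); an isolated node
  aggregates itself.  Neighborhoods are resampled every epoch
  (`resample_per_epoch=False` freezes them for debugging).  Self is never
  in N(v): the concatenation branch carries the node's own representation.
- **Normalisation backprop.** Rows with exactly zero norm (all-negative
  pre-activations under ReLU) pass through unchanged, with identity
  gradient; no NaNs arise.
- **Initialisation.** Glorot-uniform scaled by fan-in/fan-out, seeded.
- **Sample weights.** Occurrences of a node in the train list are
  aggregated into one per-node loss weight and the loss is normalised by
  the total weight, so duplicating a node is *exactly* doubling its weight,
  and gradient scale is independent of the weight mass (boosting's
  bootstrap multiplicities rely on both properties).
- **No early stopping.** The epoch count is fixed; validation metrics, if
  wanted, are monitoring only.

Because ReLU is positively homogeneous and every layer is L2-normalised,
node representations are invariant to a global rescaling of the table, so
raw counts and relative abundances are both accepted and never
renormalised.

## Boosting

Standard binary AdaBoost with three codified edge cases: ε is computed on
the full train set (not the bootstrap); a round whose learner has ε ≥ 0.5
is discarded and redrawn at most `max_retries` (default 5) times, then
skipped with a warning — the inclusive ≥ keeps every stored importance
strictly positive, and the budget prevents the literal "retry forever"
loop on degenerate data; ε is clipped to [10⁻¹⁰, 1−10⁻¹⁰] so a perfect
learner receives a large finite α rather than ∞.  The exponential update
(misclassified ×e^{+α}, correct ×e^{−α}, renormalise) leaves exactly half
the weight mass on the misclassified set — the suite tests this identity
every round.  `n_estimators` defaults to 10 (selected for the imbalanced
IBD-style cohort; 15 for the CRC-style cohort).

The continuous ranking score is the α-weighted mean of base sick-
probabilities.  Note that hard-vote labels and this soft score can disagree
near the boundary (a learner voting −1 with probability 0.45 contributes
its full −α to the vote but 0.45 to the score); the label is always the
sign of the weighted vote, ties resolving to healthy.

Base learners always see the full transductive graph, with bootstrap
multiplicities as loss weights; restricting each round to an induced
subgraph of its bootstrap would change every node's neighborhood
statistics and is deliberately not done.

## Synthetic data

The generator emulates the marginal structure of amplicon OTU tables: an
independent negative binomial per (class, feature), parameterised as
(mean μ, size r) with var = μ + μ²/r.  Fitting is method of moments
(μ̂ = mean, r̂ = μ̂²/(s²−μ̂)); closed-form and deterministic, at the price of
some efficiency versus MLE.  Under-dispersed features (s² ≤ μ̂, including
constants and all-zero features) get r = 10⁸, i.e. numerically Poisson —
no pseudocounts are injected.

The parametric "separable fixture" draws healthy means uniformly on
[5, 40], gives a fraction (default 20%) of features a sick mean multiplied
by `effect`, and uses a common dispersion r = 2 — strong overdispersion
typical of OTU counts.  What the simulator does *not* model: cross-feature
correlation, compositional closure, zero-inflation beyond the NB's own
zeros, and phylogenetic structure.  Passing tests on these cohorts
therefore demonstrate the machinery (graph construction, training,
boosting, metrics) and the imbalance handling, not performance on real
microbiomes.

## Splits, metrics, seeds

The 70:15:15 node split is stratified by label with largest-remainder
rounding per class (without stratification a 336:1023 imbalance can starve
the test partition of sick nodes).  Sick is the positive class; F1 is
defined as 0 when 2TP+FN+FP = 0; AUC uses midrank tie handling and is NaN
(with a warning) for single-class truth; AUPRC is step-wise average
precision, the construction that is unbiased under imbalance.

One master seed fans out to per-stage child seeds (simulate, split, sage,
boost, predict) through `numpy.random.SeedSequence`, so stages can be
rerun in isolation and a fixed seed reproduces a run bit-for-bit on one
machine (single-threaded).

## Problem sizes

The acceptance checks run two cohorts of 300 samples × 50 OTUs (balanced
150:150 and imbalanced 75:225), five seeds each with the median reported —
large enough for stable medians while keeping a full run in the low
minutes on one CPU; the construction oracle sweep uses 200 random 5–20
node instances, and NB recovery uses 10⁴ draws per class.

## Known limitations

- The transductive default leaks test labels into the imbalanced cap
  computation (by construction); use `blind_caps` when that matters.
- Inductive `predict(X)` on unseen samples attaches them to the fitted
  graph via the final threshold and the balanced cap — a pragmatic
  extension; the class-aware caps cannot apply since the new label is
  unknown.
- The numpy learner is dense and single-threaded; cohorts beyond a few
  thousand samples will be slow, and the N × N sampling matrices assume N
  of that order.
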