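# Methods

## Model

The package models a cohort of n independent samples observed over r
transcription factors (TFs) and t target genes. Hidden variables per
sample: a ternary status S ∈ {−1, 0, +1} for every gene; for every target
additionally the collective activator status S^A, collective inhibitor
status S^I, the regulated status S^R, and the binary deregulation indicator
D — n × (r + 5t) hidden states in total.

* **TF prior.** TF statuses are i.i.d. multinomial with proportions
  α = (α₋, α₀, α₊). One α is shared by all TFs (the pooled M-step update
  implies a single multinomial; a per-gene α would not be estimable from
  one observation per sample anyway).
* **Cooperative regulation.** A regulator set's collective status is s ∈
  {−1, +1} iff every member has status s, else 0; an empty set has status 0
  (the neutral element — this admits networks in which a target has only
  activators or only inhibitors). S^R is the truth-table function of
  (S^A, S^I) shown in the README; the table is total, so every TF
  configuration yields a well-defined expected status.
* **Deregulation.** P(D = 1) = ε; given D = 1 the realized status is
  uniform on the two states ≠ S^R, giving the per-target factor 1 − ε for
  the consistent state and ε/2 for each escaped state. (Writing the prior
  this way — rather than ε on D alone — is what makes P(D = 1) = ε and
  P(S = s | D = 1) = 1/2 hold simultaneously; the normalization constant
  log 2 is additive and therefore invisible to the M-step.)
* **Emission.** X_g | S_g = s ∼ N(µ_s, σ_s), one Gaussian triple shared by
  all genes.

The joint density factorizes over: TF priors (unary), deregulation priors
(unary on D), Gaussian evidence (unary on each S), and hard 0/1 constraints
(collective statuses, truth table, deregulation consistency).

## E-step: sum-product belief propagation

Per sample the posterior P(Z | x, θ) is represented as a discrete factor
graph. Unary factors are folded into per-variable local potentials, so the
message-passing nodes are the variables plus the multi-variable constraint
factors — approximately 2E + G nodes for E regulator→target edges and G
genes (exactly 2E + G when every regulator set has ≥ 2 members; each
singleton set adds 2 nodes and each empty set 3).

Collective-status constraints over k ≥ 2 regulators are decomposed into a
balanced binary tree of degree-3 factors implementing the pairwise combine
operator (a, b) ↦ a if a = b else 0, with auxiliary ternary variables at
internal nodes. The operator is associative and commutative under the
all-equal semantics, so the decomposition is exact; members are sorted by
gene identifier before reduction, making results independent of input edge
order. No factor ever exceeds degree 3, so one pass costs O(nodes).

Numerics and schedule:

* messages live in log space; each message is max-normalized where finite;
  hard constraints contribute −∞ entries, and all message algebra is
  addition-only (exclusive sums via prefix/suffix accumulation) so −∞
  propagates without NaN;
* the schedule is synchronous flooding — all factor→variable updates, then
  all variable→factor updates, per pass — with no damping; default 10
  passes (detection performance is flat beyond ~5, which the test suite
  checks);
* an all-(−∞) belief (contradictory constraints / impossible evidence)
  raises an error naming the variable rather than emitting NaN;
* all samples of one E-step share the graph structure and are propagated
  together along a leading batch axis; results are bit-identical to
  per-sample runs.

BP is exact on acyclic graphs (single-target networks, or targets with
disjoint regulator sets) once the pass count reaches the graph diameter; on
networks with shared regulators it is loopy BP, and marginals are
approximate. An exact enumeration oracle (`enumerate_marginals`) sums over
the 3^r TF configurations — the per-target (D, S) choices decouple given
the TFs — and is used throughout the tests as the independent reference; it
refuses instances whose joint space 3^r · 6^t exceeds ~10⁷.

## M-step, initialization, convergence

The M-step is closed form: α pools TF status marginals; ε is the mean
q(D = 1) over all (sample, target) pairs; µ_s and σ_s are posterior-
weighted moments of expression pooled over all genes (TF statuses and
targets' realized statuses). Safeguards: σ is floored at 1e−3 (Gaussian-
collapse protection); a state with zero pooled weight keeps its previous
µ, σ with a logged warning.

Initialization sets µ to the 1/6, 3/6, 5/6 pooled expression quantiles
(ordered by construction), every σ to half the pooled interquartile range,
α uniform, ε = 0.05. A constant expression matrix is rejected as
unidentifiable. The ordering µ₋ ≤ µ₀ ≤ µ₊ is imposed at initialization only
and never re-imposed during EM; label switching is possible in principle
(e.g. under extreme noise) and is documented rather than projected away.

EM stops when the mean absolute change across all 10 stored scalar
parameters (3 α + ε + 3 µ + 3 σ) drops below `tol` (default 1e−4) or after
`max_iter` (default 100) iterations. The observed-data likelihood is
intractable on loopy graphs, hence the parameter-drift criterion. Reported
scores come from a final E-step at the fitted θ, so they are posteriors
under the returned parameters. On tree networks the fitting loop can record
the exact observed-data log-likelihood per iteration (via enumeration);
monotonicity is asserted in the tests.

## Scoring and FDR control

The score of pair (i, g) is q(D_{i,g} = 1). Since scores are posterior
probabilities, among K selected pairs with score sum S the expected number
of false calls is K − S, so the FDR is estimated as (K − S)/K. Selection
ranks pairs by score descending and stops at the largest K whose estimate
stays ≤ the target level; the estimate is non-decreasing along the ranking,
so this is a prefix. Pairs tied at the threshold enter all together or not
at all — the selected set is exactly "score ≥ threshold", which makes the
realized false-discovery proportion equal 1 − precision of the PR curve at
that threshold. A 1e−10 absolute slack guards exact boundary cases against
binary round-off.

## Evaluation

Deregulation is rare (ε ≈ 0.05 by default), so performance is summarized
with precision-recall curves; AUPR uses right-continuous step integration
over distinct thresholds (the average-precision convention — the tests
cross-check against scikit-learn to 1e−12). `fdr_calibration` tabulates
intended FDR vs realized FDP against simulation truth. `sweep_experiment`
varies one parameter (σ, ε, µ, α, BP passes, gene count, sample size) with
all others at the base configuration, simulating, fitting from the default
initializer and scoring `n_replicates` fresh datasets per value.

## Synthetic data

The generator draws exactly from the generative model above, from a single
seeded stream consumed in fixed order — identical seeds give bit-identical
networks, expression and truth labels. Network topology is uniform-random
bipartite: per target an activator count in 0..max_act and inhibitor count
in 0..max_inh (redrawn until the total is between 1 and r), with distinct
TFs drawn without replacement.

Defaults define the study conditions: µ = (−1, 0, 1), shared σ = 0.3
(states separable: σ below the unit gap between means), α uniform,
ε = 0.05, degree caps 2/2, and a base sweep configuration of r = 5 TFs,
t = 10 targets, n = 30 samples — n × G = 450, in the "several hundreds"
regime where parameter recovery is stable. The heavier experiments in the
test suite use 20 samples × 30 genes (n × G = 600) for parameter recovery
and 10 replicates per sweep value.

What the generator does *not* emulate: real expression data are not
three-component Gaussian mixtures with shared component parameters across
genes; real networks are scale-free-ish with hub TFs, not uniform-random;
real deregulation is correlated across samples and genes (subtypes, CNA
segments), not i.i.d. Bernoulli. Passing tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to model misspecification on real cohorts.

## Numerical and design choices

* Degenerate inputs: genes appearing as both regulator and target are
  rejected at load time (the model assigns them different hidden-variable
  sets); expression files with missing values or duplicated columns are
  rejected with coordinates; a target FDR outside (0, 1) is an error.
* Tie-breaking: FDR selection ranks ties by sample index then target
  identifier; tree decomposition sorts regulators by identifier; both are
  purely for reproducibility.
* ε = 0 and ε = 1 are admissible (hard zeros in log space), useful for
  noise-free sanity checks.
* `enumerate_marginals` is quadratic work per sample in nothing — O(3^r t)
  — but exponential in r; it exists as an oracle and a small-instance
  fallback, not a production path.

## Known limitations

Loopy BP carries no convergence guarantee; with densely shared regulators
marginals may oscillate (the tests only assert fixed points on the
topologies exercised). A single shared emission triple (µ, σ) across genes
assumes expression has been standardized per gene; apply per-gene centering
and scaling before fitting real data. The EM objective is non-convex: the
quantile initializer is deterministic but not guaranteed to reach the
global optimum, particularly when σ approaches the gap between means.
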