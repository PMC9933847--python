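# Methods

## Setting and model

The package addresses disease-gene prioritization as positive-unlabeled
(PU) learning on a protein–protein interaction (PPI) graph.  The working
graph is undirected, simple and connected: input edge lists are cleaned by
dropping self-loops, collapsing undirected duplicates and keeping the
largest connected component (a multi-component input is a warning, not an
error, because public interactomes routinely contain stray pairs).  Nodes
are ordered lexicographically so that every matrix the pipeline builds is
reproducible down to the byte.

Seed genes carry an association score s ∈ (0, 1].  Seeds absent from the
graph are dropped with a logged count — all features are graph-functionals,
so an off-graph seed cannot contribute.  Duplicate seed rows keep the
maximum score, favouring the stronger evidence.

The method rests on two assumptions: *separability* (features can tell
positives from negatives) and *smoothness* (genes with similar features
tend to share labels).  The four features exist to make those assumptions
hold on PPI data; the labeling then exploits them.

## The four features

**Heat diffusion.**  z(t) = exp(−Lt) z(0), L = K − A, with z(0) the score
vector (0 off seeds).  Computed with the sparse action-of-the-exponential
(`scipy.sparse.linalg.expm_multiply`); the operator is never densified, and
a dense-oracle contract (agreement with direct ODE integration of
z′ = −Lz to 1e−6 at n ≤ 50) is enforced in the tests.  Mass Σz is
conserved because L has zero column sums.

**Balanced diffusion.**  Same flow with L_b = I − K⁻¹A.  The uniform
vector spans the right null space (uniform states are fixed points) and
the degree vector the left null space (Σ k z is conserved): heat diffusion
moves the same score across every *edge*, the balanced variant out of
every *node*, so the two probes weight hubs differently at short times.

**Diffusion time.**  t is a free parameter with default 0.005 for both
modes.  The features are meant to grade *proximity* to the seed set, so t
is kept small enough that score stays localized around seeds; at the
default, the diffusion columns are strongly seed-concentrated on the
synthetic graphs (typical degree 3–10), while the two path-based features
supply the longer-range gradient.  Both times are exposed in the config
and CLI for denser graphs, where a given t spreads much further.

**NetShort.**  Normalized scores s̃ᵢ = sᵢ/maxS on seeds and
penalization·minS/maxS on non-seeds (penalization default 0.5); edge
weight 2/(s̃ᵢ + s̃ⱼ); NSᵢ = Σ_{j≠i} 1/d_ij with d the exact weighted
shortest-path distance (Dijkstra, no heuristic).  With uniform s̃ this is
exactly s̃ × harmonic centrality, the oracle used in the tests.  A zero
penalization is rejected: zero scores give infinite edge weights.

**NetRing.**  Rings R(l) are multi-source BFS levels from the seed set
(R(0) = the seeds).  Initial ranks r̂ᵢ = 1 − sᵢ/maxS (seeds) or 1
(non-seeds).  Seed rank: mixing·r̂ᵢ + (1 − mixing)·mean of neighbors' r̂
(mixing default 0.5).  Non-seed rank at level l:
l + (Σ_{j∈Oᵢ} r̂ⱼ + Σ_{j∈lower ring} (rⱼ − (l−1)))/kᵢ, where Oᵢ are the
same/higher-ring neighbors.  Subtracting l−1 from a lower-ring neighbor's
rank maps it back into [0, 1], making it commensurate with r̂; the
recursion is processed ring by ring, and within a ring the order is
irrelevant because a node's rank depends only on r̂ and *lower*-ring
ranks.  Consequences proved in the tests: non-seed ranks lie in
[l, l + 1], seed ranks in [0, 1].

Raw NetRing *grows* with distance from the disease, opposite to the other
three features, so assembly flips it to max − r by default
(`invert_netring`) before normalization.  Each column is min–max
normalized to [0, 1]; a constant column becomes all zeros with a warning
rather than an error, since degenerate fixtures (complete graphs, all-seed
sets) are legitimate test inputs.  Min–max is a documented choice; any
monotone rescaling into [0, 1] would serve.

## Labeling

Pairwise squared-Euclidean feature distances e_ij are affinely rescaled to
similarities w_ij = 1 − (e_ij − m)/(M − m) over the attained off-diagonal
range, diagonal 1.  If all pairs are equidistant (includes n = 2) every
similarity is set to 1 with a warning — the propagation then still has a
connected support instead of crashing.

The similarity matrix is sparsified at the empirical q_w-quantile of its
off-diagonal entries (default q_w = 0.75; the diagonal is excluded from
the quantile because its n known 1s would bias the threshold upward).
Entries strictly below the threshold are zeroed; entries at the threshold
are kept, so the no-reduction limit q_w = 0 leaves the matrix untouched.
The unit diagonal always survives, so every row of W_r has positive sum
and W_n = D⁻¹W_r is well-defined and row-stochastic.

RN genes are the n_rn (default |P|) unlabeled genes with the largest
Euclidean distance from the mean feature vector of P, ties broken by gene
identifier.  The initial state is +1 on P, −|P|/|RN| on RN and 0
elsewhere, so it always sums to zero and the positive and negative masses
balance even when |RN| ≠ |P|.

Propagation g_r = (1 − α)W_nᵀ g_{r−1} + α g₀ uses α = 0.8, stopping when
the L2 norm of the update drops below 1e−6 (the stopping norm is a
documented choice; the row-stochastic W_n makes the iteration a
contraction with ratio ≤ 1 − α, so the geometric convergence is also
asserted as a test property).  Failure to converge within max_iter
(default 10,000) raises, carrying the last residual — a silent partial
result would poison everything downstream.

Ranking the u unlabeled genes by g_∞ (descending, ties by identifier) and
cutting with fractions (f_LP, f_WN, f_LN) gives the classes: the first
⌈f_LP·u⌉ genes are LP, the next ⌈f_WN·u⌉ (capped at what remains) WN, the
rest LN.  Ceiling-then-remainder is the fixed rounding rule; equal thirds
on u = 10 give sizes (4, 4, 2).

W is dense by construction (n² pairwise distances), which bounds the
labeling stage to roughly n ≤ 30,000 genes at 8-byte entries; the feature
stage has no such bound.

## Evaluation protocols

*Out-of-sample classification*: stratified 70/30 split (or stratified
k-fold CV; when k exceeds the smallest class, e.g. leave-one-out, plain
shuffled folds are used with a warning since stratification is then
impossible), random forest / SVM / multilayer perceptron with library
defaults and fixed seeds — the package's claims never rest on absolute
classifier scores, only on sanity properties (separable data ⇒ perfect,
shuffled labels ⇒ chance).

*Masking rediscovery*: seeds are shuffled once with the run seed and cut
into n_folds contiguous disjoint blocks of ⌈mask_fraction·|Σ|⌉; per fold,
the masked genes become ordinary unlabeled nodes in both the feature
computation and the labeling (the graph itself never changes — masking
affects seed membership only), and their assigned classes and score
statistics are tallied.  The mode of association scores is computed on
scores rounded to 2 decimals, smallest value on ties.

*Ranked candidates*: all non-P genes ordered by g_∞ descending;
precision/recall/F1 of top-k prefixes against a held-out positive set
disjoint from P.

## Synthetic data

The generator draws a planted-partition graph: edge probability p_in
inside a module of `module_size` genes, p_out elsewhere (defaults n = 300,
module 30, p_in = 0.3, p_out = 0.01 — a module of mean internal degree ≈ 9
over background degree ≈ 3, a strong but not trivial planted signal).  If
the draw is disconnected, minimal random inter-component edges are added
(logged) instead of resampling, keeping the stated probabilities honest.
A `hidden_fraction` (default 0.3) of module genes is withheld from the
seed set as gold-standard positives; the rest get scores uniform on
(0.3, 1.0], the range typical of curated association scores.  Everything
is driven by one `rng_seed`.

What the generator emulates: a connected interactome with a dense disease
module and graded seed scores.  What it does not: scale-free degree
structure, edge noise/false positives, overlapping modules, or
literature-bias in seed selection.  Tests passing on these instances
certify the machinery and its stated invariants — not performance on real
interactomes, where feature distributions are far more entangled.

One consequence at these conditions: seeds separate so cleanly in feature
space that the q_w = 0.75 sparsification removes most seed-to-unlabeled
similarity links, and unlabeled genes are ranked largely by how much
negative flow they avoid; module genes still concentrate in LP (the
masking protocol rediscovers them at rates far above the uniform-thirds
baseline), but top-k precision at very small k is tie-dominated and noisy.

## Numerical and degenerate-input choices

Quantiles via `numpy.quantile` (linear interpolation).  All sorts are
stable with (value, identifier) keys, making every output reproducible
under permutations of the input files — asserted as a test property.
Artifacts embed version and parameters in a `#` header line; two runs
with the same config and seed are byte-identical.  Feature and label
tables round floats through `%.12g`, well above the propagation tolerance.

## Known limitations

- O(n²) memory in the labeling stage (dense similarity matrix).
- Diffusion time defaults are tuned to sparse desk-scale graphs; dense
  interactomes need smaller t or per-dataset calibration.
- The classifier stage uses library-default hyperparameters; it is a
  validation harness, not a tuned predictor.
- No identifier mapping between gene symbol spaces; inputs must share one
  vocabulary.
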