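# Methods

## Model

A pathway's relation structure is a directed acyclic graph *G* over genes.
Expression is modelled as linear-Gaussian: each gene's value across *M*
conditions is normally distributed around a linear function of its parents'
values. The network score is the Bayesian Information Criterion in its
penalised-log-likelihood form,

Score(G : D) = l(θ̂_G : D) − (log M / 2) · Dim(G),

with natural logarithms throughout. θ̂_G is the maximum-likelihood fit: per
node, ordinary least squares on the parents with an intercept, and the
*maximum-likelihood* residual variance (divide by M, not M − p − 1), floored
at 1e-6 so exact linear dependencies and constant rows stay finite. Dim(G)
counts |parents| + 2 free parameters per node (coefficients, intercept,
variance). The score decomposes over node families; all search code exploits
this by caching family scores keyed on (node, parent set) and scoring each
candidate move as the exact difference of the one or two affected families.

Markov-equivalent DAGs receive identical scores under this BIC, so edge
*orientation* within an equivalence class is not identified by the data;
wherever orientation is ambiguous, scores — not edge directions — are the
meaningful quantity. Knowledge constraints partially resolve this: a
direction absent from the whitelist cannot be chosen.

## Knowledgebase and constraints

KGML pathway maps are parsed into entries (enzyme entries carry one or more
KO identifiers; compound and map-link entries carry none) and records: one
record per relation (upstream/downstream KO sets, type, optional compounds
resolved from compound entries) and one per reaction. A KGML reaction names
a single catalysing entry rather than an upstream/downstream pair, so its
record stores that entry's KO set on both sides together with its substrate
and product compounds; through the index this still produces cross-gene
edges between distinct genes sharing the KO. Relations whose endpoints are
unknown or KO-free are skipped with a logged warning and counted, since real
maps contain placeholder entries. An exclusion list lets a caller keep a
target organism's own maps out of the index.

The ordered KO-pair index expands every record by the cartesian product of
its upstream and downstream KO sets. Gene-level projection expands again
over all genes carrying each KO; self-pairs are never emitted (a Bayesian
network has no self-loops). Constraint assembly produces two sets: required
edges (the seed pathway's, pinned during search) and allowed edges (the
knowledgebase projection over the candidate genes, unioned with the required
edges so a seed edge is never illegal). Edges outside the allowed set are
excluded absolutely.

Seed pathways come from marking reference-map enzyme entries whose KO sets
intersect a gene's assignments (any-KO intersection) and expanding the map's
records over the marked genes. Metabolic maps often contain directed cycles,
which a Bayesian network cannot carry; cycle-forming seed edges are demoted
deterministically (the lexicographically smallest edge of each detected
cycle is removed first) until the seed is a DAG. Demoted relations remain
reachable through the whitelist whenever the reference map's records are in
the knowledgebase, so search may reintroduce them in a consistent
orientation. Seed genes lacking expression data are dropped and logged.

## Search

Greedy hill climbing from the seed graph. Each iteration enumerates every
legal move — add (whitelisted non-edges only), remove and reverse (never a
required edge; a reversal additionally requires the reversed direction to be
whitelisted, the stricter reading of knowledge-constrained moves) — subject
to acyclicity, applies the single best score delta, and stops when no move
improves by more than 1e-9 (the tolerance prevents floating-point livelock).
Ties break deterministically: add < remove < reverse, then lexicographic
edge order. The required ⊆ edges ⊆ allowed and acyclicity invariants are
re-verified at every accepted state. A restart count is exposed in the API
surface as plain re-invocation with different seeds; the default is a single
pass.

Known limitation: single-pass hill climbing cannot traverse plateaus of
score-equivalent states, so on data with strong dependencies it can stop at
a local optimum whose equivalence class differs from the global one
(observed on roughly 10–25 % of small dense linear-Gaussian instances,
depending on density). The exhaustive enumerator (≤ 5 genes; subsets of the
allowed edges containing the required ones, acyclicity-checked, ties toward
fewer edges then lexicographic edge lists) exists precisely to measure this
gap; on unstructured instances greedy attains the optimum essentially
always.

## Expression preprocessing and clustering

Genes with *strictly more than* 20 % missing values are removed (exactly
20 % is kept); the threshold is configurable. Remaining gaps are imputed by
the gene's observed mean (default) or by k-nearest-neighbour (k = 10): the
neighbours of a gap are the genes observed at that condition, ranked by root
mean squared difference over jointly observed conditions. Observed entries
pass through bit-identically. No normalisation or batch correction is
applied.

Clustering uses a diagonal-covariance Gaussian mixture fitted by EM:
k-means++-style seeded initial means, four seeded restarts keeping the best
final training log-likelihood (plain random initialisation merged well-
separated components often enough to distort model selection), convergence
at relative log-likelihood change < 1e-6 or 500 iterations, variances
floored at 1e-6. All randomness flows from one explicit seed. The component
count is chosen by cross-validation over gene folds (10-fold default,
reduced automatically when there are fewer genes): the k in the search range
with the highest mean per-gene held-out log-likelihood wins, ties toward the
smaller k.

## Gene sampling

The pivotal cluster is the one containing the most seed-pathway genes (ties
toward the lower index). Per-cluster sampling weights are proportional to
1/(1 + d) with d the Euclidean distance between cluster means — this keeps
the pivot's weight finite and maximal; the exact decay form is a design
choice recorded in run metadata. The number of genes to draw is the
round-half-up mean enzyme-entry count of the reference maps (floor 1).
Draws are without replacement: pick a cluster by weight (renormalising over
non-exhausted clusters), then a uniform unused gene within it. Each
stochastic run re-samples its own gene set.

## Evaluation

Edge recall = true positives / target edges, precision = true positives /
predicted edges, zero (not NaN) on empty denominators. Directed matching is
the default; undirected mode collapses orientations first and is reported
when cyclic target maps make orientation comparisons unfair. Precision is
additionally reported with required (seeded) edges excluded from the
prediction, since seeded edges are not discoveries. Repeated runs are
summarised by minimum, lower quartile, median, upper quartile, and maximum
with linear (type-7) interpolation — stated in the output because plotting
conventions differ. Method comparison counts per-instance strict median
wins and ties separately.

## Synthetic benchmarks

A bundle derives everything from one seed via spawned seed sequences:
a truth DAG (random topological order, i.i.d. edge inclusion; density in
(0, 1], the closed end giving the full DAG), expression by ancestral
sampling (roots N(0, σ²); children add coefficient-weighted parents;
coefficient magnitudes uniform in `coef_range` with random sign — the
default (0.8, 0.8) gives the ±0.8 study condition; σ = 1), a one-KO-per-gene
assignment table (a multi-KO mode exercises the cartesian-expansion paths),
and two KGML documents: a reference map carrying a random 50 % of the true
edges (the incomplete homology seed) and a knowledgebase map carrying the
noisy whitelist (truth minus drops, plus 50 % decoy non-edges, plus the seed
edges so required ⊆ allowed always holds) with one synthetic compound per
true edge. Defaults — 8–12 genes, M = 500–1,000, coefficients ±0.8, noise
σ = 1, decoy fraction 0.5 — make desk-scale recovery statistically
comfortable while keeping every experiment seconds-fast.

What the generator does *not* emulate: real expression covariance structure
(no shared technical noise, no non-Gaussian tails, no batch effects), KEGG
map topology statistics, multi-subunit enzyme complexes, or cyclic target
networks. Passing benchmarks therefore demonstrate the machinery —
constraint handling, score fidelity, the benefit of a mostly-correct
whitelist — not performance on real organisms, where the knowledgebase is
far noisier and the linear-Gaussian assumption is an approximation.

## Standing experiments

`pathwaybn.benchmarks` (driven by `scripts/acceptance.py` and the test
suite) fixes the experiment sizes: 100 four-gene random-data instances at
M = 500 for greedy-vs-exhaustive optimality; 50 bundles (n = 8, M = 1,000,
50 % decoys) comparing constrained learning (seed graph + whitelist) with
unconstrained learning (empty start, all pairs) on the same data; 20
mixture draws (3 components, 30 genes each, pairwise mean separation 6σ,
5-fold CV over k ∈ 1..6) for cluster-count recovery; 20 random 8-gene
fixtures for KGML round-trips; and 20 random graphs at M = 200 checked
against a directly coded score computation. These sizes are the package's
chosen desk-scale study conditions; every quantity is recomputed at run
time from the given seed.
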