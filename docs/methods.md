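# Methods

## Problem and model

Given an undirected PPI network G(V, E) with positive edge weights w_ij
(reliability/strength scores of the kind produced by log-likelihood or
socioaffinity scoring of heterogeneous experimental evidence), the task is
binary classification of connected triplets: does a set of three distinct,
connected proteins form a heterotrimeric complex? A triplet counts as
connected when at least two of its three possible edges are present (any
two edges on three vertices connect all three, so the test reduces to an
edge count).

Both classifiers are kernel machines on precomputed Gram matrices
G[i,j] = ⟨f(x_i), f(x_j)⟩ + α·K_c(x_i, x_j). The inner product is over raw
feature values — no scaling is applied by default, since the features are
all on the weight scale or small counts and the soft margin absorbs the
remaining imbalance. K_c is the 0/1 domain composition kernel; it is
positive semidefinite (a block matrix of ones over equivalence classes), so
the combined Gram is PSD for α ≥ 0. Signature computation sorts each
protein's domain multiset and then sorts the three per-protein
compositions; equality of these canonical forms realises the
"exists a permutation" test without iterating over the symmetric group.
Domain counts are multiset cardinalities: a repeated domain counts twice,
consistently in F6/F7 and in K_c equivalence.

## Feature conventions

F1/F2 range only over internal edges actually present (for a path triplet
with two equal edges, F1 = F2 = that weight). When a triplet has no
external neighbour, F3 = F4 = F5 = 0 — the same zero convention the
phase-2 features use on empty sets, and the "no evidence of a competing
complex" extreme. For F5, an external protein adjacent to all three
members contributes the best min over member pairs, i.e. the second
largest of its three weights.

## Two-phase learning

Phase 1 is a soft-margin SVM (C = 1.0 by default, the common solver
default; the cost is exposed in the configuration) on the f⁽¹⁾ Gram.
Discriminant values for the training triplets are taken in-sample from the
phase-1 model fitted on the full training fold; no inner cross-validation
is performed (configurable extensions are possible, but the simple reading
keeps one fit per fold and reuses it). Neighbour triplets are scored
through cross-kernel rows against the training set; they need no labels,
and N(x) is computed over the whole network, not only over labelled
examples, excluding only x itself. Discriminants and per-triplet features
are memoised per (network, annotation) pair because neighbourhoods overlap
heavily; the cache is shared across folds.

Phase-2 features obey f⁽²ⁿ⁾ ≤ f⁽²ᵃ⁾ ≤ f⁽²ᵖ⁾ (the overall mean is a convex
combination of the positive-part and negative-part means, with zeros
counted on both sides of the strict inequalities). Classification uses the
sign of the phase-2 discriminant with the tie y = 0 mapped to the negative
class — conservative for precision.

An optional cap on |N(x)| (default: unlimited) bounds the cost on hub
proteins by keeping the neighbours with the largest maximum internal
weight.

## Sparse Bayesian second classifier

The relevance vector machine uses the logistic link σ(y) = 1/(1+e^{-y})
and a zero-mean Gaussian prior with per-weight precision γ_i. Fitting is
sequential sparse Bayesian learning: starting from the bias basis alone,
each outer iteration (i) finds the posterior mode of the active weights by
Newton/IRLS with backtracking under the Laplace approximation, (ii)
computes the sparsity/quality statistics s_m, q_m of every basis against
the current working response, and (iii) applies the single
add/re-estimate/delete action with the largest analytic marginal-likelihood
gain. Because the analytic gain holds only for the frozen linearisation,
each action is trial-applied and kept only if the re-linearised Laplace
marginal likelihood actually improves by more than the tolerance
(tol = 1e-6); otherwise the next-best candidate (up to 8) is tried, and
when none improves the fit has converged. This keeps the recorded
likelihood history monotone and prevents re-estimate cycling between
correlated bases. Precisions are capped at γ = 1e12 (beyond which a basis
is numerically pruned; pruned weights are exactly zero). The default
iteration budget is 500; non-convergence is flagged on the model rather
than raised. There is no random initialisation, so fits are deterministic.
The basis matrix is used as given and need not be positive semidefinite.

## Evaluation protocol

Dataset construction mirrors the intended use: positives are all size-3
catalogue complexes connected in the network; the negative pool is every
connected 3-subset of a larger complex that is not itself a catalogue
heterotrimer; negatives are a uniform sample without replacement
(default 100). Cross-validation is stratified (with on the order of
80 positives and 100 negatives, unstratified 10-fold splits risk
positive-free folds), repeated with fresh negative samples while keeping
all positives. Within a fold, confusion counts are pooled and the four
metrics computed per fold, then averaged over folds and repeats
(pooled-per-repeat aggregation is available behind a flag).
Zero-denominator metrics are defined as 0, so an all-negative fold yields
precision = F = 0 rather than an error. All randomness derives from a
single integer seed; runs are bit-reproducible.

## Synthetic data

The generator plants heterotrimers as triangles and larger complexes as
cliques, both with internal weights from a truncated normal (default mean
50, sd 10), over a background of Erdős–Rényi edges with weaker weights
(default mean 10, sd 5, edge probability 0.02) among all proteins
(100 extra background proteins by default). Weights are redrawn up to ten
times to stay positive, then floored. With overlap probability 0 (the
default, matching the premise that heterotrimers rarely share proteins)
planted trimers are vertex-disjoint. Domains are assigned uniformly at
random (0–4 per protein from 30 types), so the domain features carry
little class signal by default; an optional per-trimer shared signature can
inject K_c signal. All sub-streams (topology, weights, domains) come from
spawned children of one seeded generator.

The benchmark used by the acceptance script plants 80 heterotrimers and
12 size-5..7 complexes, so the connected-negative pool is at least
12·C(5,3) = 120 for every seed and a 100-negative sample always exists —
matching the scale of an 80-positive/100-negative study design. Ten
generator seeds with one 10-fold cross-validation each keep the full
benchmark under a minute on one CPU.

What the generator does *not* emulate: the heavy-tailed degree
distribution of real interactomes, correlated experimental noise across
edges, biologically structured domain architectures, and partially
observed complexes. Passing the planted benchmarks therefore demonstrates
that the pipeline recovers the signal its features are designed for — high
internal weights, weak boundaries, doubly-attached outsiders — not that it
attains any particular performance on a real interactome. With the default
weight separation the planted task is easy (F-measure 1.0 for both
single-phase and two-phase); the second phase's advantage is expected to
appear when triplet features alone are ambiguous, and on these planted
conditions the comparison reads "not worse", not "strictly better".

## Known limitations

- Neighbour enumeration is exact; on hub-dominated real networks |N(x)|
  can grow large, for which the cap option exists but defaults off.
- Phase-1 training discriminants are in-sample, which can be optimistic
  for the phase-2 features when folds are small.
- The RVM implementation targets the problem sizes here (hundreds of
  examples); it inverts the active-basis Hessian directly and is not tuned
  for thousands of bases.
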