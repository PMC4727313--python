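# Methods

## Dendrograms and canonical forms

All trees handled here are rooted, strictly binary and leaf-labeled:
leaves have degree 1, the root degree 2, every other internal node degree 3,
and leaf labels are unique. Multifurcating inputs are rejected rather than
collapsed: a multifurcation is a different modelling choice (one tree that
*aggregates* tied merges), whereas this package enumerates the binary
alternatives a tie admits. Branch lengths and internal node labels are
accepted on Newick input and ignored; the contrast functions depend only on
topology, and indeed are invariant under any positive rescaling of the
input distances.

The canonical form orders the two children of every node by the
lexicographically smallest leaf label in their subtrees, and the canonical
key of a node concatenates its children's keys in that order. Key equality
therefore decides rooted leaf-labeled isomorphism, and serialized Newick
output (which uses the same order) is deterministic. A rooted binary
leaf-labeled tree is uniquely determined by the set of leaf sets of its
nontrivial subtrees, so "cluster C is a branch of D" can be decided by key
membership in D's subtree-key family; this is how the graph contrast is
implemented, avoiding repeated set-of-sets comparisons.

## Tie-branching enumeration

Input is a labeled symmetric dissimilarity matrix (validated for symmetry,
zero diagonal, non-negativity), or a feature table from which Euclidean
distances are computed with scipy's `pdist`. At each agglomeration step
the search finds the minimum inter-cluster dissimilarity `d*` and treats as
tied every pair with

```
d <= d* + max(abs_tol, rel_tol * d*),    abs_tol = 0, rel_tol = 1e-9.
```

Ties of interest are exact equalities, but the Lance–Williams updates run
in floating point, so a small relative tolerance is needed to recognize
equalities that are exact in real arithmetic but differ in the last ulp
(e.g. distances involving a planted `sqrt(12)` coordinate). `abs_tol` is
available for genuinely imprecise data but defaults to zero. A relative
tolerance also preserves the invariance of the enumerated set under
positive rescaling of all distances.

The search branches depth-first on every tied pair, merging it at height
`d*` and updating distances by the Lance–Williams rule of the selected
linkage:

| linkage | update for `d(i∪j, k)` | a.k.a. |
|---------|------------------------|--------|
| `group_average` | `(n_i d_ik + n_j d_jk)/(n_i + n_j)` | UPGMA (default) |
| `simple_average` | `(d_ik + d_jk)/2` | WPGMA |
| `single` | `min(d_ik, d_jk)` | nearest neighbor |
| `complete` | `max(d_ik, d_jk)` | furthest neighbor |

Completed trees are deduplicated by canonical key: different orders of
merging disjoint tied pairs reach the same topology, and a frequency is a
statement about *distinct* dendrograms, each counted once. Search states —
the canonical keys of the active clusters together with their pairwise
distances — are memoized, so a state reached along two merge orders is
expanded only once. The memo is sound because the set of completions of a
state depends only on that state. When the number of distinct trees reaches
the cap (default 200,000) the search stops and the result is flagged
`capped`; frequencies computed over a capped set are estimates on a partial
enumeration and the flag is propagated into reports. A tie log records,
along the first path explored, the minimum distance and the number of tied
pairs at each step.

Items at distance zero (e.g. attribute columns identical across all items)
are not merged implicitly; `dedupe_zero_distance` collapses each
zero-distance equivalence class to one representative up front, keeping the
reduction explicit and reportable.

Two independent oracles check the enumeration. `felsenstein_count(n)`
computes `F(n) = (2n−3)!/(2^{n−2}(n−2)!)` in exact integer arithmetic
(`F(1) = F(2) = 1`); `enumerate_all_topologies` constructs every rooted
binary topology once by recursive leaf insertion (a new leaf can attach
above any of the `2k − 1` nodes of a `k`-leaf tree). On an equidistant
matrix — every off-diagonal distance equal, the maximal-tie case — the
tie-branching enumeration must return exactly the `F(n)` topologies
produced by the direct construction, and it does, for every linkage, since
all linkage updates preserve full equidistance. In the opposite extreme
(all distances and all updated distances distinct) exactly one dendrogram
is returned, and it coincides with scipy's `linkage` output.

## Contrasts and frequencies

The four contrast functions and the frequency estimator are implemented
over the canonical-key and leaf-set families described above. All values
are exact `fractions.Fraction`s; floating point enters only at report time,
where the display default of 2 decimals renders 1/3 as 0.33. (Note that a
chained product of *rounded* frequencies, e.g. 0.5 × 0.33 = 0.165, differs
from the exact 1/6 ≈ 0.1667 in the third decimal; the package reports
exact values and rounds once, at the end.)

The relaxed contrasts maximize a Jaccard index over **all** nontrivial
subtrees of the dendrogram, the root included. Singleton subtrees never
enter any family, so a shared single leaf contributes nothing; the relaxed
graph contrast is positive exactly when the cluster and the dendrogram
share a cherry (a two-leaf subtree), which the tests verify against a
brute-force cherry scan.

Ordering and equivalence laws, all property-tested on seeded random
instances: `CC_g ≤ CC_rg`, `CC_s ≤ CC_rs`, `CC_g ≤ CC_s`,
`CC_rg = 1 ⇔ CC_g = 1`, `CC_rg = 0 ⇒ CC_g = 0`, `CC_s = 1 ⇔ CC_rs = 1`.
For a two-leaf cluster, `CC_g`, `CC_rg` and `CC_s` coincide and are 0/1,
and `CC_rs = 1` exactly when they equal 1. `CC_rs` alone can sit strictly
between 0 and 1 in that case — the root's leaf set always overlaps a valid
query, so `CC_rs > 0` whenever the query's leaves are a subset of the
tree's; it is the only contrast that can credit a cluster no subtree
matches exactly.

A cluster supplied only as a leaf set cannot be graph-contrasted; asking
for `g`/`rg` on a set-only query is a hard error rather than a silent
fallback to the set contrasts, because the two readings answer different
questions and can disagree on the same input.

The frequency estimator accepts any nonempty dendrogram collection sharing
one leaf set — tie-derived or otherwise (linkage sweeps, resampling, noise
injection) — which turns it into a general cluster-stability measure. In
the equidistant case the graph frequency of any cluster with `k` leaves is
`F(n − k + 1)/F(n)`: contracting the cluster to a single pseudo-leaf puts
the trees containing it in bijection with the topologies on `n − k + 1`
leaves. The measured frequency over the enumerated set matches this closed
form exactly in the tests, for every cluster size at `n = 3, 4, 5`.

## Synthetic data

The generators produce every input the tests and examples need; nothing is
downloaded and everything is a pure function of its arguments, seed
included.

- `toy_table1` — nine points in the plane in three well-separated groups,
  with ties planted exactly: one group with a forced internal structure,
  one with a binary tie (a point equidistant from two others, via integer
  coordinates), one an equilateral triangle whose apex coordinate
  `6 + sqrt(12)` makes the three pairwise distances all equal 4. Between
  groups, the group-average merge order is strictly resolved, so the
  enumeration factorizes as 1 × 2 × 3 = 6 dendrograms.
- `equidistant_space(n, c)` — the maximal-tie case; `c` is any positive
  constant (the enumerated set is invariant to it).
- `random_tied_matrix(n, n_levels, seed)` — distances drawn uniformly from
  `n_levels` discrete values, emulating coarse-precision data. Levels are
  spaced on `[1, 1.5]`: keeping all values within a factor of two of each
  other guarantees the triangle inequality, so every draw is a metric.
  Fewer levels mean more ties; the tests verify the resulting monotone
  trend in the expected number of dendrograms by a small Monte-Carlo sweep
  over seeds.
- `separated_clusters_with_ties(k, sizes, separation, seed)` — each cluster
  is a regular simplex (an exact local equidistant space; exactness by
  construction, not rounding), centers are placed on a perfect difference
  set so every between-cluster distance is distinct, and the total
  enumerated count factorizes as the product of per-cluster counts.

What these generators do *not* emulate: the distance distributions of real
molecular-descriptor tables, correlated attributes, or near-ties that fall
inside a data-collection error bar rather than machine epsilon. Passing
tests show the enumeration and the estimators are correct on inputs whose
tie structure is known exactly; on real data the practical questions are
the choice of `abs_tol` (should two distances equal to measurement
precision count as tied?) and the combinatorial growth of `m`, which the
cap and the sampling driver are there to manage, not to answer.

## Problem sizes and numerical choices

The test suite and the acceptance script run the toy example (9 leaves, 6
dendrograms), equidistant spaces up to `n = 6` (945 topologies), sampling
experiments with 10–20 repetitions at submatrix size 5, and randomized
property sweeps of a few hundred (cluster, tree) pairs on up to 8 leaves —
sizes at which the brute-force oracles remain exact cross-checks and the
whole suite completes in seconds. The enumeration cap defaults to 200,000
distinct trees, comfortably above anything these sizes can produce; it
exists because real descriptor matrices are documented to admit six-figure
dendrogram counts.

Tie-break order within the search is immaterial to the result (the output
is a set, deduplicated and sorted by canonical key); display rounding is
half-even via Python's `round`; frequencies are exact rationals end to end.

## Known limitations

- Exponential worst case: an equidistant matrix on `n` leaves has `F(n)`
  dendrograms, so the enumeration is for desk-scale `n` or for data whose
  ties are localized; the cap turns explosion into a flagged partial
  result, not an error.
- Only the four listed linkages are implemented; Ward-style
  merging-criterion ties and non-Euclidean similarity inputs are out of
  scope (a pre-computed distance matrix of any origin is accepted, though).
- Unrooted trees, multifurcations and branch-length-aware tree distances
  (e.g. Robinson–Foulds) are deliberately unsupported.
- Frequencies over a capped enumeration are relative to the partial set;
  no bound on the truncation error is attempted.
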