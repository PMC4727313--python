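# tieclust

Tie-aware hierarchical clustering: dendrogram enumeration, cluster
contrasts and cluster-frequency estimation.

## The problem

Agglomerative hierarchical clustering (HCA) merges, at every step, the pair
of clusters at minimum dissimilarity. When two or more pairs are *tied* at
that minimum — an equidistance, or **tie in proximity** — the merge is
non-unique, and different tie-breaking choices produce different
dendrograms. Standard implementations break ties silently (typically by
input order) and report a single tree, so any conclusion drawn from "the"
dendrogram may be an artifact of row ordering. Ties are common whenever
data are discrete or of limited precision — a typical situation when
clustering molecular descriptors for QSAR feature selection, where a
classification built on one arbitrary dendrogram among thousands of equally
valid ones is unlikely to be reliable.

`tieclust` makes the multiplicity explicit. It enumerates **every distinct
dendrogram** reachable by breaking ties in all possible ways, and then
measures how often a given cluster appears across that set (or across any
other set of dendrograms sharing one leaf set — e.g. trees from parameter
sweeps or noise injection), giving an empirical probability for each
clustering pattern.

## The model

A dendrogram `D` on a leaf set `X` (`n = |X|`) is a rooted, strictly binary,
leaf-labeled tree. Each internal node (root included) defines a
*nontrivial subtree* (≥ 2 leaves); there are exactly `n − 1` of them. Two
families summarize `D`:

- `P(D)` — the set of its nontrivial subtrees (as graphs),
- `N(D) = { s_j }` — their leaf sets, `s_j = L(g_j)`.

A candidate cluster `C` can be given as a graph (a small tree, Newick) or as
a bare leaf set `L(C)`. Four **contrast functions** score its presence in
`D`, from most to least stringent:

| tag | name | definition |
|-----|------|------------|
| `g` | graph | `1` iff `C ∈ P(D)` (C is a branch of D, or D itself) |
| `rg` | relaxed graph | `max_j J(P(C), P(g_j))` over `g_j ∈ P(D)` |
| `s` | set | `1` iff `L(C) ∈ N(D)` |
| `rs` | relaxed set | `max_j J(L(C), s_j)` over `s_j ∈ N(D)` |

where `J(A,B) = |A ∩ B| / |A ∪ B|` is the Jaccard index (on canonical
subtree keys for `rg`, on leaf labels for `rs`). The **frequency** of `C`
over a dendrogram set `{D_i}, i ≤ m` is the mean contrast

```
f_j(C) = (1/m) Σ_i CC_j(C, D_i),        j ∈ {g, rg, s, rs},
```

i.e. the empirical probability of the cluster. The number of possible
rooted binary topologies on `n` leaves is `F(n) = (2n−3)! / (2^{n−2}(n−2)!)`,
and always `m ≤ F(n)`. In the maximal-tie case (all distances equal) the
enumeration reaches all `F(n)` topologies and the graph frequency has the
closed form `f_g(C) = F(n − |L(C)| + 1) / F(n)`.

Enumeration works by depth-first tie branching: at each agglomeration step
the minimum inter-cluster dissimilarity `d*` is found, and the merge is
tried for every pair with `d ≤ d* + max(abs_tol, rel_tol·d*)`; distances
are updated by the Lance–Williams rule of the chosen linkage
(`group_average` = UPGMA, `simple_average` = WPGMA, `single`, `complete`)
and completed trees are deduplicated by a canonical form invariant under
child reordering.

## Worked example

Nine points in the plane form three well-separated groups
`A = {a,b,c}`, `B = {g,h,i}`, `C = {d,e,f}`, with ties planted inside `B`
(i equidistant from g and h) and `C` (an equilateral triangle):

```python
from tieclust import (ClusterQuery, enumerate_dendrograms,
                      euclidean_matrix, frequency)
from tieclust.fixtures import toy_table1

result = enumerate_dendrograms(euclidean_matrix(toy_table1()),
                               linkage="group_average")
print(result.m)
for tree in result.trees:
    print(" ", tree.newick())
for q in ["(a,b);", "(g,i);", "(d,e);"]:
    f = frequency(ClusterQuery.from_newick(q), result.trees, method="g")
    print(q, f, float(f))
```

prints

```
6
  ((((a,b),c),((g,i),h)),((d,e),f));
  ((((a,b),c),((g,i),h)),((d,f),e));
  ((((a,b),c),((g,i),h)),(d,(e,f)));
  ((((a,b),c),(g,(h,i))),((d,e),f));
  ((((a,b),c),(g,(h,i))),((d,f),e));
  ((((a,b),c),(g,(h,i))),(d,(e,f)));
(a,b); 1 1.0
(g,i); 1/2 0.5
(d,e); 1/3 0.3333333333333333
```

Read: the ties admit 6 distinct dendrograms, not one. The cherry `(a,b)`
is forced (frequency 1, it appears in all six trees); `(g,i)` competes with
the tied alternative `(h,i)` (frequency 0.5 each); `(d,e)` is one of three
equally likely starts inside the equilateral triangle (frequency 1/3).
Each complete dendrogram, taken as a cluster itself, has frequency 1/6.

The same pipeline is available from the shell:

```sh
tieclust enumerate --input toy.csv --input-kind features --out trees.nwk
tieclust freq --trees trees.nwk --clusters clusters.txt \
              --methods g,rg,s,rs --out freq.tsv
tieclust sample --input dist.csv --fraction 0.25 --reps 100 --seed 1 \
                --out samples.tsv
```

`enumerate` writes one Newick tree per line (exit status 3 if the
enumeration hit the cap and the file is partial); `freq` accepts graph-form
clusters (Newick lines) and set-form clusters (comma-separated leaf lists)
and writes a TSV of frequencies; `sample` repeatedly restricts a distance
matrix to a random label subset and records how many dendrograms each
submatrix admits.

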