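"""Tie-aware agglomerative clustering with exhaustive tie branching.

Ordinary agglomerative clustering breaks ties in proximity arbitrarily and
reports one dendrogram.  Here every tie is branched on: at each step the
minimum inter-cluster dissimilarity d* is found and the merge is attempted
for *every* pair within tolerance of d*, recursing depth-first and collecting
all completed trees.  Distinct topologies (by canonical key) form the
enumerated set {D_i}, i <= m, over which cluster frequencies are averaged.

The number of possible rooted binary leaf-labeled topologies on n leaves is
F(n) = (2n-3)! / (2^{n-2} (n-2)!), and m <= F(n) always; on an equidistant
matrix (the maximal-tie case) the enumeration reaches every one of the F(n)
topologies.  A brute-force all-topologies enumerator is provided as the
independent oracle for that case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .trees import Dendrogram, Node

__all__ = [
    "DistanceMatrix",
    "EnumerationResult",
    "LINKAGES",
    "euclidean_matrix",
    "enumerate_dendrograms",
    "felsenstein_count",
    "enumerate_all_topologies",
    "dedupe_zero_distance",
]

#: Lance-Williams update rules: d(i∪j, k) from d(i,k), d(j,k) and cluster sizes.
LINKAGES = ("group_average", "simple_average", "single", "complete")

DEFAULT_CAP = 200_000


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix.

    ``labels`` is the ordered item list and ``values`` the square array of
    pairwise dissimilarities (zero diagonal, symmetric).
    """

    labels: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        v = np.asarray(self.values, dtype=float)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if n < 2:
            raise ValueError("need at least 2 items")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < 0).any():
            raise ValueError("negative dissimilarities")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def restrict(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Principal submatrix on the given labels (order preserved)."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        """Build from a square labeled DataFrame; a lower-triangular frame
        (NaN above the diagonal) is mirrored."""
        v = df.to_numpy(dtype=float)
        upper = np.triu_indices_from(v, k=1)
        if np.isnan(v[upper]).all() and v.shape[0] > 1:
            v = np.where(np.isnan(v), v.T, v)
        diag = np.diag(v).copy()
        if np.isnan(diag).any():
            v = v.copy()
            np.fill_diagonal(v, np.where(np.isnan(diag), 0.0, diag))
        return cls(tuple(str(i) for i in df.index), v)

    @classmethod
    def read_csv(cls, path, sep: Optional[str] = None) -> "DistanceMatrix":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls.from_frame(pd.read_csv(path, sep=sep, index_col=0))

    def write_csv(self, path, sep: Optional[str] = None) -> None:
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        self.to_frame().to_csv(path, sep=sep)


@dataclass
class EnumerationResult:
    """Outcome of a tie-branching enumeration.

    ``trees`` holds the distinct dendrograms (no two share a canonical key),
    ``m = len(trees)``, ``capped`` flags a search stopped at the cap (the set
    is then partial), and ``tie_log`` records, for the first path explored,
    one ``(step, min_distance, n_tied_pairs)`` triple per agglomeration step.
    """

    trees: List[Dendrogram]
    capped: bool
    tie_log: List[Tuple[int, float, int]] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.trees)

    def canonical_keys(self) -> frozenset:
        return frozenset(t.canonical_key for t in self.trees)


def euclidean_matrix(features: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances of a feature table (rows = items)."""
    if features.shape[0] < 2:
        raise ValueError("need at least 2 items")
    labels = tuple(str(i) for i in features.index)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate item labels in feature table")
    if features.isna().any().any():
        raise ValueError("feature table contains missing values")
    d = squareform(pdist(features.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(labels, d)


def _lw_update(linkage: str, d_ik: float, d_jk: float, n_i: int, n_j: int) -> float:
    if linkage == "group_average":
        return (n_i * d_ik + n_j * d_jk) / (n_i + n_j)
    if linkage == "simple_average":
        return 0.5 * (d_ik + d_jk)
    if linkage == "single":
        return min(d_ik, d_jk)
    if linkage == "complete":
        return max(d_ik, d_jk)
    raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")


class _CapReached(Exception):
    pass


def enumerate_dendrograms(
    dist: DistanceMatrix,
    linkage: str = "group_average",
    abs_tol: float = 0.0,
    rel_tol: float = 1e-9,
    cap: int = DEFAULT_CAP,
) -> EnumerationResult:
    """Enumerate all distinct dendrograms reachable by breaking ties.

    At each agglomeration step the minimum inter-cluster dissimilarity d* is
    computed and every pair with d <= d* + max(abs_tol, rel_tol * d*) is a
    tied candidate; the search branches once per candidate, updates distances
    by the Lance-Williams rule of ``linkage``, and recurses.  Completed trees
    are deduplicated by canonical key.  States already visited (same active
    clusters and same inter-cluster distances) are pruned, since their
    completions are already collected.

    Raises nothing on combinatorial explosion: when the number of distinct
    trees reaches ``cap`` the search stops and the result is flagged
    ``capped`` (the tree set is then partial).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if abs_tol < 0 or rel_tol < 0:
        raise ValueError("tolerances must be >= 0")
    if cap < 1:
        raise ValueError("cap must be >= 1")

    n = dist.n
    leaves = [Node.leaf(l) for l in dist.labels]
    init_d = {
        frozenset((i, j)): float(dist.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }

    results: Dict[str, Dendrogram] = {}
    seen_states = set()
    tie_log: List[Tuple[int, float, int]] = []
    logged_depth = set()
    capped = False

    def recurse(active: Dict[int, Tuple[Node, int]], dmat: Dict, depth: int):
        if len(active) == 1:
            (node, _size), = active.values()
            if node.key not in results:
                if len(results) >= cap:
                    raise _CapReached
                results[node.key] = Dendrogram(node)
            return

        sig = frozenset(
            (frozenset((active[i][0].key, active[j][0].key)), d)
            for (i, j), d in ((tuple(p), d) for p, d in dmat.items())
        )
        if sig in seen_states:
            return
        seen_states.add(sig)

        d_star = min(dmat.values())
        cutoff = d_star + max(abs_tol, rel_tol * d_star)
        tied = [pair for pair, d in dmat.items() if d <= cutoff]

        if depth not in logged_depth:
            logged_depth.add(depth)
            tie_log.append((depth, d_star, len(tied)))

        next_id = max(active) + 1
        for pair in tied:
            i, j = tuple(pair)
            node_i, size_i = active[i]
            node_j, size_j = active[j]
            merged = Node.join(node_i, node_j, height=dmat[pair])

            new_active = {k: v for k, v in active.items() if k not in (i, j)}
            new_active[next_id] = (merged, size_i + size_j)

            new_d = {}
            for p, d in dmat.items():
                if i in p or j in p:
                    continue
                new_d[p] = d
            for k in new_active:
                if k == next_id:
                    continue
                d_ik = dmat[frozenset((i, k))]
                d_jk = dmat[frozenset((j, k))]
                new_d[frozenset((next_id, k))] = _lw_update(
                    linkage, d_ik, d_jk, size_i, size_j
                )
            recurse(new_active, new_d, depth + 1)

    active0 = {i: (leaves[i], 1) for i in range(n)}
    try:
        recurse(active0, init_d, 1)
    except _CapReached:
        capped = True

    trees = sorted(results.values(), key=lambda t: t.canonical_key)
    return EnumerationResult(trees=trees, capped=capped, tie_log=tie_log)


def felsenstein_count(n: int) -> int:
    """Number of rooted binary leaf-labeled topologies on n leaves:
    F(n) = (2n-3)! / (2^{n-2} (n-2)!), exact; F(1) = F(2) = 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n <= 2:
        return 1
    return math.factorial(2 * n - 3) // (2 ** (n - 2) * math.factorial(n - 2))


def enumerate_all_topologies(leaves: Sequence[str], bound: int = 8) -> List[Dendrogram]:
    """Every rooted binary leaf-labeled topology on the given leaves, exactly
    once, by recursive leaf insertion (attach the new leaf above each existing
    node in turn).  The count equals ``felsenstein_count(len(leaves))``."""
    labels = sorted(set(str(l) for l in leaves))
    if len(labels) != len(list(leaves)):
        raise ValueError("duplicate leaf labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    if len(labels) > bound:
        raise ValueError(
            f"{len(labels)} leaves exceed the bound {bound} "
            f"(F({len(labels)}) = {felsenstein_count(len(labels))} topologies)"
        )

    def insert(node: Node, new_leaf: Node) -> List[Node]:
        # attach above `node` itself, or recurse into either child
        out = [Node.join(node, new_leaf)]
        if not node.is_leaf:
            a, b = node.children
            out.extend(Node.join(sub, b) for sub in insert(a, new_leaf))
            out.extend(Node.join(a, sub) for sub in insert(b, new_leaf))
        return out

    roots = [Node.join(Node.leaf(labels[0]), Node.leaf(labels[1]))]
    for label in labels[2:]:
        roots = [r for root in roots for r in insert(root, Node.leaf(label))]
    return [Dendrogram(r) for r in roots]


def dedupe_zero_distance(
    dist: DistanceMatrix, tol: float = 0.0
) -> Tuple[DistanceMatrix, Dict[str, List[str]]]:
    """Collapse items at zero distance to a single representative.

    Items whose pairwise dissimilarity is <= ``tol`` are grouped (transitive
    closure); the first label in input order represents each group.  Returns
    the reduced matrix and a representative -> members mapping.  Mirrors the
    pre-clustering step of dropping attribute columns that are identical
    across all items, keeping the reduction explicit.
    """
    n = dist.n
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dist.values[i, j] <= tol:
                parent[find(i)] = find(j)

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    reps = sorted(min(members) for members in groups.values())
    mapping = {
        dist.labels[min(members)]: [dist.labels[i] for i in sorted(members)]
        for members in groups.values()
    }
    if len(reps) < 2:
        raise ValueError("fewer than 2 items remain after deduplication")
    reduced = DistanceMatrix(
        tuple(dist.labels[i] for i in reps), dist.values[np.ix_(reps, reps)]
    )
    return reduced, mapping
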