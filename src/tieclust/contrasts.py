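"""Cluster-contrast functions and the cluster-frequency estimator.

A cluster ``C`` can be read two ways: as a *graph* (a candidate branch, with
its own internal hierarchy) or as a *set* (just its leaf labels L(C)).  Each
reading has a strict and a relaxed contrast against a dendrogram ``D``:

* graph contrast         CC_g  = 1 iff C is a branch of D (or D itself);
* relaxed graph contrast CC_rg = max_j J(P(C), P(g_j)) over the nontrivial
  subtrees g_j of D, where J is the Jaccard index on subtree-key sets;
* set contrast           CC_s  = 1 iff L(C) is the leaf set of some subtree;
* relaxed set contrast   CC_rs = max_j J(L(C), s_j) over the subtree leaf
  sets s_j of D.

The frequency of C over a dendrogram set {D_i}, i <= m, sharing one leaf set
is the mean contrast f_j(C) = (1/m) * sum_i CC_j(C, D_i) -- the empirical
probability of the cluster across the set.  The set may come from tie
branching or from any other source (parameter sweeps, noise injection), which
makes f_j a general cluster-stability measure.

In the maximal-tie (equidistant) case the graph frequency has a closed form:
f_g(C) = F(n - |L(C)| + 1) / F(n), with F the rooted-topology count.
Contrasts and frequencies are returned as exact :class:`fractions.Fraction`
values; rendering to decimals happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .linkage_enum import felsenstein_count
from .trees import Dendrogram, parse_newick

__all__ = [
    "ClusterQuery",
    "FrequencyReport",
    "METHODS",
    "cc_graph",
    "cc_relaxed_graph",
    "cc_set",
    "cc_relaxed_set",
    "contrast",
    "frequency",
    "tiecase_graph_frequency",
    "frequency_report",
]

#: method tags: g = graph, rg = relaxed graph, s = set, rs = relaxed set
METHODS = ("g", "rg", "s", "rs")


@dataclass(frozen=True)
class ClusterQuery:
    """A cluster to contrast: a leaf set, optionally with graph structure.

    ``tree`` is present for graph-form queries (parsed from Newick); set-only
    queries can use only the set contrasts.  When both are present the
    tree's leaf set and ``leaf_set`` coincide by construction.
    """

    id: str
    leaf_set: frozenset
    tree: Optional[Dendrogram] = None

    def __post_init__(self):
        if len(self.leaf_set) < 2:
            raise ValueError("a cluster needs at least 2 leaves")
        if self.tree is not None and self.tree.leaves != self.leaf_set:
            raise ValueError("graph form and leaf set disagree")

    @classmethod
    def from_newick(cls, text: str, id: Optional[str] = None) -> "ClusterQuery":
        tree = parse_newick(text)
        return cls(id=id or text.strip(), leaf_set=tree.leaves, tree=tree)

    @classmethod
    def from_leaves(
        cls, leaves: Iterable[str], id: Optional[str] = None
    ) -> "ClusterQuery":
        leaf_set = frozenset(str(l) for l in leaves)
        return cls(id=id or ",".join(sorted(leaf_set)), leaf_set=leaf_set)

    @classmethod
    def parse(cls, line: str) -> "ClusterQuery":
        """One cluster per line: trailing ';' means Newick (graph form),
        otherwise a comma-separated leaf list (set form)."""
        line = line.strip()
        if line.endswith(";"):
            return cls.from_newick(line)
        return cls.from_leaves(x.strip() for x in line.split(","))

    @property
    def has_graph(self) -> bool:
        return self.tree is not None


def _require_graph(cluster: ClusterQuery) -> Dendrogram:
    if cluster.tree is None:
        raise ValueError(
            f"cluster {cluster.id!r} has no graph form; "
            "graph contrasts need a Newick cluster, not a leaf list"
        )
    return cluster.tree


def _require_subset(cluster: ClusterQuery, tree: Dendrogram) -> None:
    if not cluster.leaf_set <= tree.leaves:
        extra = sorted(cluster.leaf_set - tree.leaves)
        raise ValueError(
            f"cluster {cluster.id!r} has leaves {extra} absent from the dendrogram"
        )


def cc_graph(cluster: ClusterQuery, tree: Dendrogram) -> Fraction:
    """Strict graph contrast: 1 iff the cluster, with its internal structure,
    is a branch of the dendrogram (the whole dendrogram counts)."""
    c = _require_graph(cluster)
    _require_subset(cluster, tree)
    key = c.canonical_key
    return Fraction(int(key in tree.subtree_partition()))


def cc_relaxed_graph(cluster: ClusterQuery, tree: Dendrogram) -> Fraction:
    """Relaxed graph contrast: the best Jaccard overlap between the cluster's
    subtree partition P(C) and the partition P(g_j) of any nontrivial subtree
    g_j of the dendrogram."""
    c = _require_graph(cluster)
    _require_subset(cluster, tree)
    pc = c.subtree_partition()
    best = Fraction(0)
    for pg in tree.subtree_partitions_by_node():
        inter = len(pc & pg)
        if inter:
            j = Fraction(inter, len(pc | pg))
            if j > best:
                best = j
    return best


def cc_set(cluster: ClusterQuery, tree: Dendrogram) -> Fraction:
    """Strict set contrast: 1 iff the cluster's leaf set is exactly the leaf
    set of some nontrivial subtree of the dendrogram."""
    _require_subset(cluster, tree)
    return Fraction(int(cluster.leaf_set in tree.leafset_family()))


def cc_relaxed_set(cluster: ClusterQuery, tree: Dendrogram) -> Fraction:
    """Relaxed set contrast: the best Jaccard overlap between the cluster's
    leaf set and the leaf set of any nontrivial subtree of the dendrogram."""
    _require_subset(cluster, tree)
    lc = cluster.leaf_set
    best = Fraction(0)
    for s in tree.leafset_family():
        inter = len(lc & s)
        if inter:
            j = Fraction(inter, len(lc | s))
            if j > best:
                best = j
    return best


_CONTRASTS = {
    "g": cc_graph,
    "rg": cc_relaxed_graph,
    "s": cc_set,
    "rs": cc_relaxed_set,
}


def contrast(cluster: ClusterQuery, tree: Dendrogram, method: str) -> Fraction:
    """Dispatch to one of the four contrast functions by method tag."""
    try:
        fn = _CONTRASTS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return fn(cluster, tree)


def _check_shared_leaves(trees: Sequence[Dendrogram]) -> frozenset:
    if not trees:
        raise ValueError("empty dendrogram set")
    leaves = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaves:
            raise ValueError("dendrograms do not share one leaf set")
    return leaves


def frequency(
    cluster: ClusterQuery, trees: Sequence[Dendrogram], method: str = "g"
) -> Fraction:
    """Mean contrast of the cluster over a dendrogram set sharing one leaf
    set: the cluster's empirical probability.  The set may be tie-derived or
    arbitrary (stability use); each distinct dendrogram counts once."""
    leaves = _check_shared_leaves(trees)
    if not cluster.leaf_set <= leaves:
        raise ValueError(
            f"cluster {cluster.id!r} is not a subset of the shared leaf set"
        )
    total = sum(contrast(cluster, t, method) for t in trees)
    return Fraction(total, len(trees)) if total else Fraction(0)


def tiecase_graph_frequency(n: int, cluster_size: int) -> Fraction:
    """Closed-form graph frequency in the equidistant (maximal-tie) case:
    F(n - cluster_size + 1) / F(n).  Depends only on cluster size, so
    equal-size clusters are equally likely; < 1 whenever the cluster has at
    least two leaves and n > 2."""
    if not 2 <= cluster_size <= n:
        raise ValueError("cluster_size must lie in [2, n]")
    k = n - cluster_size + 1
    return Fraction(felsenstein_count(k), felsenstein_count(n))


@dataclass
class FrequencyReport:
    """Per-cluster, per-method frequency table.

    ``rows`` are (cluster_id, method, frequency as Fraction); ``m`` is the
    number of dendrograms averaged over and ``capped`` whether that set was
    truncated at the enumeration cap (frequencies are then lower/upper
    estimates on a partial set).
    """

    rows: List[Tuple[str, str, Fraction]]
    m: int
    capped: bool = False

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Tabular form: display-rounded and full-precision frequency."""
        data = [
            {
                "cluster_id": cid,
                "method": method,
                "frequency": round(float(f), decimals),
                "frequency_exact": float(f),
                "m": self.m,
                "capped": int(self.capped),
            }
            for cid, method, f in self.rows
        ]
        return pd.DataFrame(
            data,
            columns=[
                "cluster_id",
                "method",
                "frequency",
                "frequency_exact",
                "m",
                "capped",
            ],
        )

    def write_tsv(self, path, decimals: int = 2) -> None:
        self.to_frame(decimals=decimals).to_csv(path, sep="\t", index=False)


def frequency_report(
    clusters: Sequence[ClusterQuery],
    trees: Sequence[Dendrogram],
    methods: Sequence[str] = METHODS,
    capped: bool = False,
) -> FrequencyReport:
    """Frequencies for every cluster x method combination."""
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    rows = [
        (c.id, m, frequency(c, trees, m)) for c in clusters for m in methods
    ]
    return FrequencyReport(rows=rows, m=len(trees), capped=capped)
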