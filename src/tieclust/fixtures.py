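"""Deterministic generators for test and demonstration inputs.

Everything needed to exercise the enumeration and the contrast functions is
generated in memory: the nine-point toy layout with planted ties, equidistant
metric spaces (the maximal-tie case), low-precision random matrices with a
controlled number of distinct distance levels, and well-separated clusters
whose only ties are internal.  All generators are pure functions of their
arguments, seed included.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .linkage_enum import DistanceMatrix

__all__ = [
    "toy_table1",
    "equidistant_space",
    "random_tied_matrix",
    "separated_clusters_with_ties",
    "write_feature_table",
]

# Centers drawn from a perfect difference set, so every center-to-center
# distance is distinct and between-cluster merges are never tied.
_SIDON = (0, 1, 3, 7, 12, 20, 30, 44, 59, 75)


def toy_table1() -> pd.DataFrame:
    """Nine points in the plane forming three well-separated groups with
    planted ties.

    Group {a,b,c}: a-b closer than the (tied) a-c / b-c pair, so the internal
    structure is forced.  Group {g,h,i}: i equidistant from g and h (one
    binary tie).  Group {d,e,f}: an equilateral triangle -- the coordinate
    6 + sqrt(12) makes the three pairwise distances exactly equal (all 4) --
    i.e. a three-point equidistant space.
    """
    data = {
        "P1": [1.0, 2.0, 1.5, 10.0, 14.0, 12.0, 0.0, 2.0, 1.0],
        "P2": [1.0, 1.0, 2.0, 6.0, 6.0, 6.0 + math.sqrt(12.0), 9.0, 11.0, 10.0],
    }
    return pd.DataFrame(data, index=list("abcdefghi"))


def equidistant_space(n: int, c: float = 1.0) -> DistanceMatrix:
    """All off-diagonal dissimilarities equal to ``c``: the maximal-tie case.
    Labels are x1..xn."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if c <= 0:
        raise ValueError("c must be > 0")
    v = np.full((n, n), float(c))
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(tuple(f"x{i + 1}" for i in range(n)), v)


def random_tied_matrix(n: int, n_levels: int, seed: int) -> DistanceMatrix:
    """Random symmetric matrix whose distances take only ``n_levels``
    distinct values, emulating low-precision or coarsely discretized data.

    Fewer levels mean more ties, hence more enumerated dendrograms.  Levels
    are spaced in [1, 1.5]; keeping all values within a factor of two of each
    other guarantees the triangle inequality, so the output is a metric.
    ``n_levels = 1`` degenerates to an equidistant space.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    rng = np.random.default_rng(seed)
    levels = np.linspace(1.0, 1.5, n_levels)
    v = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    draws = rng.choice(levels, size=len(iu[0]))
    v[iu] = draws
    v = v + v.T
    return DistanceMatrix(tuple(f"x{i + 1}" for i in range(n)), v)


def _simplex(size: int, edge: float = 1.0) -> np.ndarray:
    """Coordinates of a regular simplex with the given edge length: ``size``
    points in R^size, all pairwise distances equal."""
    pts = np.eye(size) * edge / math.sqrt(2.0)
    return pts


def separated_clusters_with_ties(
    k_clusters: int,
    sizes: Sequence[int],
    separation: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table of well-separated clusters whose only ties are internal.

    Each cluster is a regular simplex (all within-cluster distances exactly
    equal -- a local equidistant space), placed at centers whose pairwise
    distances are all distinct, so between-cluster merge order is strictly
    resolved and enumerated dendrograms differ only in within-cluster
    structure.  The enumerated count therefore factorizes as the product of
    the per-cluster counts.  ``seed`` shuffles which center each cluster
    occupies.  Labels are c<k>_<i>.
    """
    sizes = list(sizes)
    if k_clusters < 1 or len(sizes) != k_clusters:
        raise ValueError("sizes must list one size per cluster")
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be >= 1")
    if k_clusters > len(_SIDON):
        raise ValueError(f"at most {len(_SIDON)} clusters supported")
    if separation <= 4 * max(sizes):
        raise ValueError("separation too small relative to within-cluster spread")

    rng = np.random.default_rng(seed)
    centers = separation * np.array(_SIDON[:k_clusters], dtype=float)
    order = rng.permutation(k_clusters)

    dim = max(sizes)
    rows, labels = [], []
    for k, size in enumerate(sizes):
        pts = np.zeros((size, dim + 1))
        pts[:, 1:size + 1] = _simplex(size)
        pts[:, 0] += centers[order[k]]
        for i in range(size):
            rows.append(pts[i])
            labels.append(f"c{k + 1}_{i + 1}")
    cols = [f"a{j + 1}" for j in range(dim + 1)]
    return pd.DataFrame(rows, index=labels, columns=cols)


def write_feature_table(df: pd.DataFrame, path, sep: Optional[str] = None) -> None:
    """Write a feature table in the CSV/TSV dialect the CLI reads (first
    column = labels)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index_label="label")
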