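"""Agglomerative clustering, dendrogram cutting, the elbow heuristic,
bi-clustering, metadata aggregation and Newick export.

The clusterer is a deterministic agglomerative scheme over six vector
metrics (Euclidean, Manhattan, 1-D Earth Mover's, Chebyshev, Canberra and
Pearson-correlation distance) and three linkages (single, complete and
unweighted-average/UPGMA).  At every step the pair of clusters at minimal
linkage distance is merged; ties are broken by the lexicographically
smallest pair of cluster indices, which makes the merge trace reproducible
across platforms.  Inter-cluster distances are maintained with the
Lance-Williams update formulas, which are exact for these three linkages.

Cutting the dendrogram into k groups undoes the k-1 highest merges and
yields a pattern set: memberships, per-pattern counts, centroid
representatives and a label taken from the first member in leaf order.
The elbow heuristic suggests k from the profile of merge-height variance
across candidate cuts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ClusteringError
from .space import GenometricSpace, _check_axis

METRICS = ("EU", "MA", "EA", "CH", "CA", "PE")
LINKAGES = ("SINGLE", "AVERAGE", "COMPLETE")


def distance(u, v, metric: str) -> float:
    """Distance between two equal-length numeric vectors.

    EU, MA and CH are the usual Minkowski-family metrics.  CA (Canberra)
    sums ``|u_i - v_i| / (|u_i| + |v_i|)`` with 0/0 terms counted as 0.
    EA is the 1-D earth mover's distance for vectors read as signatures
    over ordered, unit-spaced bins: the summed absolute prefix
    differences.  PE is ``1 - r`` with r the Pearson product-moment
    correlation; it is undefined (an error) on zero-variance vectors.
    """
    metric = metric.upper()
    if metric not in METRICS:
        raise ClusteringError(f"unknown metric {metric!r}")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ClusteringError("vectors must be 1-D and of equal length")
    diff = u - v
    if metric == "EU":
        return float(np.sqrt(np.sum(diff * diff)))
    if metric == "MA":
        return float(np.sum(np.abs(diff)))
    if metric == "CH":
        return float(np.max(np.abs(diff))) if diff.size else 0.0
    if metric == "CA":
        num = np.abs(diff)
        den = np.abs(u) + np.abs(v)
        terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        return float(terms.sum())
    if metric == "EA":
        return float(np.sum(np.abs(np.cumsum(diff))))
    # PE
    if u.size < 2:
        raise ClusteringError("Pearson distance needs vectors of length >= 2")
    uc = u - u.mean()
    vc = v - v.mean()
    su = float(np.dot(uc, uc))
    sv = float(np.dot(vc, vc))
    if su == 0.0 or sv == 0.0:
        raise ClusteringError(
            "Pearson correlation undefined for a zero-variance vector")
    r = float(np.dot(uc, vc)) / math.sqrt(su * sv)
    return 1.0 - r


def pairwise_distances(X: np.ndarray, metric: str) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = distance(X[i], X[j], metric)
    return D


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree produced by agglomerative clustering.

    Leaves are numbered 0..n-1 in the clustered axis's original order;
    merge m creates cluster ``n + m``.  ``merges`` lists
    ``(left, right, height)`` with ``left < right`` and height equal to
    the inter-cluster distance at the merge.  ``leaves`` gives element
    ids in left-to-right traversal order, which is also the permutation
    applied to the clustered space.
    """

    element_ids: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]
    axis: str
    linkage: str
    metric: str

    def __post_init__(self):
        if len(self.merges) != max(len(self.element_ids) - 1, 0):
            raise ClusteringError(
                f"{len(self.element_ids)} leaves require "
                f"{len(self.element_ids) - 1} merges, got {len(self.merges)}")

    @property
    def n_leaves(self) -> int:
        return len(self.element_ids)

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(h for _, _, h in self.merges)

    def leaf_order(self) -> tuple[int, ...]:
        """Left-to-right traversal order as original leaf indices."""
        n = self.n_leaves
        if n == 1:
            return (0,)
        children = {n + m: (left, right)
                    for m, (left, right, _) in enumerate(self.merges)}
        order: list[int] = []
        stack = [n + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                left, right = children[node]
                stack.append(right)
                stack.append(left)
        return tuple(order)

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(self.element_ids[i] for i in self.leaf_order())

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "linkage": self.linkage,
            "metric": self.metric,
            "elements": list(self.element_ids),
            "merges": [{"left": l, "right": r, "height": h}
                       for l, r, h in self.merges],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Dendrogram":
        return cls(element_ids=tuple(payload["elements"]),
                   merges=tuple((m["left"], m["right"], m["height"])
                                for m in payload["merges"]),
                   axis=payload.get("axis", "rows"),
                   linkage=payload.get("linkage", "AVERAGE"),
                   metric=payload.get("metric", "EU"))


def linkage_merges(X: np.ndarray, linkage: str, metric: str
                   ) -> list[tuple[int, int, float]]:
    """Merge trace of agglomerative clustering on the rows of *X*.

    Maintains the full inter-cluster distance matrix indexed by cluster
    id (leaves first, merged clusters after) and updates it with the
    Lance-Williams recurrences.  The argmin scan is row-major over
    ascending cluster ids, which realizes the smallest-pair tie-break.
    """
    linkage = linkage.upper()
    if linkage not in LINKAGES:
        raise ClusteringError(f"unknown linkage {linkage!r}")
    n = X.shape[0]
    if n < 2:
        raise ClusteringError("clustering needs at least 2 elements")
    total = 2 * n - 1
    D = np.full((total, total), np.inf)
    base = pairwise_distances(X, metric)
    iu = np.triu_indices(n, k=1)
    D[iu] = base[iu]
    size = np.ones(total)
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        act = np.array(active)
        sub = D[np.ix_(act, act)]
        flat = int(np.argmin(sub))  # first minimum in row-major order
        i = int(act[flat // len(act)])
        j = int(act[flat % len(act)])
        height = float(D[i, j])
        new = n + step
        for k in active:
            if k in (i, j):
                continue
            d_ki = D[min(k, i), max(k, i)]
            d_kj = D[min(k, j), max(k, j)]
            if linkage == "SINGLE":
                d = min(d_ki, d_kj)
            elif linkage == "COMPLETE":
                d = max(d_ki, d_kj)
            else:  # unweighted average (UPGMA)
                d = ((size[i] * d_ki + size[j] * d_kj)
                     / (size[i] + size[j]))
            D[k, new] = d
        size[new] = size[i] + size[j]
        active = [k for k in active if k not in (i, j)] + [new]
        merges.append((i, j, height))
    return merges


def cluster(space: GenometricSpace, axis: str, linkage: str, metric: str
            ) -> tuple[GenometricSpace, Dendrogram]:
    """Cluster one axis of a space; returns the reordered space and the
    dendrogram.  Missing cells are imputed as 0 for distance computation
    (with a warning); the returned space keeps its original values."""
    axis = _check_axis(axis)
    X = space.values if axis == "rows" else space.values.T
    element_ids = space.row_ids if axis == "rows" else space.col_ids
    if X.shape[0] < 2:
        raise ClusteringError(f"clustering needs at least 2 {axis}")
    if np.isnan(X).any():
        warnings.warn("missing cells imputed as 0 for distance computation",
                      stacklevel=2)
        X = np.nan_to_num(X, nan=0.0)
    merges = linkage_merges(np.asarray(X, dtype=float), linkage, metric)
    dendrogram = Dendrogram(element_ids=tuple(element_ids),
                            merges=tuple(merges), axis=axis,
                            linkage=linkage.upper(), metric=metric.upper())
    order = dendrogram.leaf_order()
    if axis == "rows":
        reordered = space.take(order, None)
    else:
        reordered = space.take(None, order)
    return reordered, dendrogram


def bicluster(space: GenometricSpace
              ) -> tuple[GenometricSpace, Dendrogram, Dendrogram]:
    """Cluster rows and columns simultaneously (complete linkage,
    Euclidean distance).  The result is a terminal artifact: it is meant
    for display/export and takes no further transitions in a state tree."""
    if space.n_rows < 2 or space.n_cols < 2:
        raise ClusteringError("bi-clustering needs at least 2 rows and "
                              "2 columns")
    by_rows, row_dendro = cluster(space, "rows", "COMPLETE", "EU")
    reordered, col_dendro = cluster(by_rows, "columns", "COMPLETE", "EU")
    return reordered, row_dendro, col_dendro


@dataclass(frozen=True)
class PatternSet:
    """A cut of a dendrogram into k patterns.

    ``membership`` maps element id -> pattern index; indices run 0..k-1
    in order of first appearance along the dendrogram's leaf order, so
    pattern 0 is the leftmost.  ``labels`` carries the name of the first
    leaf of each pattern and ``centroids`` the per-pattern mean vector
    (when the associated space was provided to :func:`cut`).
    """

    k: int
    axis: str
    membership: dict
    counts: tuple[int, ...]
    labels: tuple[str, ...]
    centroids: np.ndarray | None = None

    def members(self, pattern: int) -> tuple[str, ...]:
        return tuple(e for e, p in self.membership.items() if p == pattern)


def cut(dendrogram: Dendrogram, k: int,
        space: GenometricSpace | None = None) -> PatternSet:
    """Cut the dendrogram into *k* patterns by undoing the k-1 highest
    merges (ties resolved toward later merges)."""
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ClusteringError(f"k={k} out of range 1..{n}")
    order = sorted(range(len(dendrogram.merges)),
                   key=lambda m: (dendrogram.merges[m][2], m))
    undone = set(order[len(order) - (k - 1):]) if k > 1 else set()

    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (left, right, _) in enumerate(dendrogram.merges):
        if m in undone:
            continue
        c = n + m
        parent[find(left)] = find(c)
        parent[find(right)] = find(c)

    leaf_order = dendrogram.leaf_order()
    pattern_of_root: dict[int, int] = {}
    membership: dict[str, int] = {}
    for leaf in leaf_order:
        root = find(leaf)
        if root not in pattern_of_root:
            pattern_of_root[root] = len(pattern_of_root)
        membership[dendrogram.element_ids[leaf]] = pattern_of_root[root]
    if len(pattern_of_root) != k:
        raise ClusteringError(
            f"cut produced {len(pattern_of_root)} groups instead of {k}; "
            "the dendrogram is structurally inconsistent")

    counts = [0] * k
    for p in membership.values():
        counts[p] += 1
    labels: list[str] = [""] * k
    seen = set()
    for leaf in leaf_order:
        p = membership[dendrogram.element_ids[leaf]]
        if p not in seen:
            labels[p] = dendrogram.element_ids[leaf]
            seen.add(p)

    centroids = None
    if space is not None:
        X = space.values if dendrogram.axis == "rows" else space.values.T
        ids = (space.row_ids if dendrogram.axis == "rows"
               else space.col_ids)
        index = {e: i for i, e in enumerate(ids)}
        centroids = np.full((k, X.shape[1]), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for p in range(k):
                rows = [index[e] for e, q in membership.items()
                        if q == p and e in index]
                if rows:
                    centroids[p] = np.nanmean(X[rows], axis=0)
    return PatternSet(k=k, axis=dendrogram.axis, membership=membership,
                      counts=tuple(counts), labels=tuple(labels),
                      centroids=centroids)


def elbow_suggest(dendrogram: Dendrogram, k_max: int | None = None) -> int:
    """Suggest a cluster count from the dendrogram's merge heights.

    For each candidate k, the explained fraction is the (population)
    variance of the heights of the merges undone by cutting into k
    groups, divided by the total variance of all merge heights.  The
    suggestion is the k at which the slope of this curve increases most
    between consecutive candidates — the knee of the profile.  A
    degenerate dendrogram whose merge heights are all equal yields 1
    with a warning.
    """
    n = dendrogram.n_leaves
    if n < 3:
        raise ClusteringError("elbow suggestion needs at least 3 leaves")
    if k_max is None:
        k_max = min(n - 1, 50)
    if not (3 <= k_max <= n):
        raise ClusteringError(f"k_max={k_max} out of range 3..{n}")
    heights = np.array(dendrogram.heights, dtype=float)
    total_var = float(np.var(heights))
    if total_var == 0.0 or not np.isfinite(total_var):
        warnings.warn("all merge heights equal; no elbow, suggesting k=1",
                      stacklevel=2)
        return 1
    # heights of undone merges for cut(k): the k-1 highest, later merges
    # winning ties — sort ascending by (height, merge index), take the tail
    order = sorted(range(len(heights)), key=lambda m: (heights[m], m))
    sorted_desc = [heights[m] for m in reversed(order)]
    pct = [0.0] * (k_max + 2)  # pct[k] for k = 1..k_max
    for k in range(1, k_max + 1):
        top = sorted_desc[: k - 1]
        pct[k] = float(np.var(top)) / total_var if len(top) >= 2 else 0.0
    slope = {k: pct[k + 1] - pct[k] for k in range(1, k_max)}
    best_k, best_diff = 1, -np.inf
    for k in range(2, k_max):
        diff = slope[k] - slope[k - 1]
        if diff > best_diff + 1e-12:
            best_k, best_diff = k, diff
    return best_k


def metadata_counts(patterns: PatternSet, space: GenometricSpace
                    ) -> pd.DataFrame:
    """Aggregate occurrences of each metadata attribute-value pair per
    pattern.

    For column patterns the pairs come from sample metadata; for row
    patterns the reference-region attributes are rendered as pairs.
    Returns a table indexed by (attribute, value), one column per
    pattern, ordered by attribute then value.
    """
    if patterns.axis == "columns":
        pair_lists = {cid: list(meta)
                      for cid, meta in zip(space.col_ids, space.col_meta)}
    else:
        pair_lists = {
            rid: [(name, str(value))
                  for name, value in region.attributes.items()
                  if value is not None]
            for rid, region in zip(space.row_ids, space.row_regions)}
    tally: dict[tuple[str, str], list[int]] = {}
    for element, pattern in patterns.membership.items():
        for pair in pair_lists.get(element, ()):  # no metadata -> nothing
            if pair not in tally:
                tally[pair] = [0] * patterns.k
            tally[pair][pattern] += 1
    index = pd.MultiIndex.from_tuples(sorted(tally),
                                      names=["attribute", "value"])
    data = [tally[pair] for pair in sorted(tally)]
    return pd.DataFrame(data, index=index,
                        columns=[f"P-{p}" for p in range(patterns.k)])


def to_newick(dendrogram: Dendrogram, normalize: bool = False) -> str:
    """Export the dendrogram as a Newick string with branch lengths.

    The tree is ultrametric: a cluster merged at height h sits at depth
    h/2 above the leaves, so a 2-leaf dendrogram of height h renders as
    ``(A:x,B:x);`` with x = h/2.  With ``normalize=True`` all root-to-leaf
    path lengths are rescaled to 1.
    """
    n = dendrogram.n_leaves
    if n == 1:
        return f"{_newick_name(dendrogram.element_ids[0])}:0;"
    depth = {leaf: 0.0 for leaf in range(n)}
    for m, (_, _, h) in enumerate(dendrogram.merges):
        depth[n + m] = h / 2.0
    root = n + len(dendrogram.merges) - 1
    scale = 1.0
    if normalize and depth[root] > 0:
        scale = depth[root]
    children = {n + m: (left, right)
                for m, (left, right, _) in enumerate(dendrogram.merges)}

    text: dict[int, str] = {}
    # children before parents: merge order guarantees that
    for leaf in range(n):
        text[leaf] = _newick_name(dendrogram.element_ids[leaf])
    for m in range(len(dendrogram.merges)):
        node = n + m
        left, right = children[node]
        parts = []
        for child in (left, right):
            length = (depth[node] - depth[child]) / scale
            parts.append(f"{text[child]}:{length:.10g}")
        text[node] = "(" + ",".join(parts) + ")"
    return text[root] + ";"


def _newick_name(name: str) -> str:
    out = []
    for ch in str(name):
        out.append("_" if ch in "(),:; \t'\"[]" else ch)
    return "".join(out)
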