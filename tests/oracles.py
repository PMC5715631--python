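"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's own implementation
paths: overlap joins are naive double loops, aggregates go through the
statistics module, agglomerative merges recompute every inter-cluster
distance from scratch at every step, and the LRU model is a plain
recency list.
"""

from __future__ import annotations

import statistics


def naive_overlap(a, b) -> bool:
    return (a.chromosome == b.chromosome
            and max(a.start, b.start) < min(a.end, b.end))


def naive_aggregate(bag, tag):
    tag = tag.upper()
    if tag == "COUNT":
        return float(len(bag))
    if not bag:
        return float("nan")
    if tag == "MIN":
        return float(min(bag))
    if tag == "MAX":
        return float(max(bag))
    if tag == "SUM":
        return float(sum(bag))
    if tag == "AVERAGE":
        return float(sum(bag)) / len(bag)
    if tag == "MEDIAN":
        return float(statistics.median(bag))
    raise ValueError(tag)


def naive_map(reference, experiments, attribute, aggregate):
    """O(|R| * |S_j|) double-loop MAP join; returns a nested list."""
    out = []
    for ref_region in reference.regions:
        row = []
        for exp in experiments:
            bag = []
            for region in exp.regions:
                if naive_overlap(ref_region, region):
                    bag.append(1.0 if attribute is None
                               else float(region.attributes[attribute]))
            row.append(naive_aggregate(bag, aggregate))
        out.append(row)
    return out


def naive_linkage_trace(leaf_distances, linkage):
    """Agglomerative merge trace recomputing all pairwise cluster
    distances from their leaf members at every step.

    ``leaf_distances[i][j]`` is the distance between leaves i and j.
    Clusters are numbered like the implementation: leaves 0..n-1, merge m
    creates n+m.  Ties break toward the lexicographically smallest pair.
    """
    n = len(leaf_distances)
    members = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        ids = sorted(members)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                cross = [leaf_distances[x][y]
                         for x in members[a] for y in members[b]]
                if linkage == "SINGLE":
                    d = min(cross)
                elif linkage == "COMPLETE":
                    d = max(cross)
                else:
                    d = sum(cross) / len(cross)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        new = n + step
        members[new] = members.pop(a) + members.pop(b)
        merges.append((a, b, d))
    return merges


def threshold_partition(merges, n, k):
    """Partition from keeping the n-k lowest merges (height, then merge
    order), i.e. thresholding just above the k-th largest merge."""
    order = sorted(range(len(merges)), key=lambda m: (merges[m][2], m))
    kept = set(order[: n - k])
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            x = parent[x] = parent[parent[x]]
        return x

    for m in kept:
        left, right, _ = merges[m]
        parent[find(left)] = find(n + m)
        parent[find(right)] = find(n + m)
    return [find(leaf) for leaf in range(n)]


class LRUModel:
    """Reference least-recently-used cache over hashable keys."""

    def __init__(self, capacity):
        self.capacity = capacity
        self.recency = []  # least recent first

    def touch(self, key):
        if key in self.recency:
            self.recency.remove(key)
        self.recency.append(key)

    def resident(self):
        return set(self.recency[-self.capacity:])
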