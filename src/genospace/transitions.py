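"""Pure matrix transformations: Extract, Rewrite, Discretize and Sort.

Each transformation maps a :class:`~genospace.space.GenometricSpace` to a
new one and can be described by a :class:`TransitionSpec`, a small
JSON-serializable record.  Applying the same spec to the same space always
reproduces the identical output, which is what makes evicted exploration
states reconstructable by replay.

Index ranges are written ``[lower, upper)`` (inclusive lower, exclusive
upper) and always refer to the *current* order of the space, i.e. after
any earlier sorting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import TransitionError
from .space import GenometricSpace, _check_axis, _region_field

OPS = ("EXTRACT", "REWRITE", "DISCRETIZE", "SORT", "CLUSTER", "BICLUSTER")


@dataclass(frozen=True)
class TransitionSpec:
    """A replayable description of one transformation."""

    op: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        op = self.op.upper()
        if op not in OPS:
            raise TransitionError(f"unknown operation {self.op!r}")
        object.__setattr__(self, "op", op)
        object.__setattr__(self, "params", dict(self.params))

    def to_dict(self) -> dict:
        return {"op": self.op, "params": json.loads(self.to_json())["params"]}

    def to_json(self) -> str:
        return json.dumps({"op": self.op, "params": self.params},
                          sort_keys=True)

    @classmethod
    def from_dict(cls, payload: dict) -> "TransitionSpec":
        return cls(op=payload["op"], params=payload.get("params", {}))

    @classmethod
    def from_json(cls, text: str) -> "TransitionSpec":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class RangeRule:
    """One Rewrite rule: map values in the closed interval
    ``[v_min, v_max]`` to a constant or to their log in a given base."""

    v_min: float
    v_max: float
    value: float | None = None
    log_base: float | None = None

    def __post_init__(self):
        if self.v_min > self.v_max:
            raise TransitionError(
                f"rule interval [{self.v_min}, {self.v_max}] is empty")
        if (self.value is None) == (self.log_base is None):
            raise TransitionError(
                "exactly one of a constant value or a log base is required")
        if self.log_base is not None and (self.log_base <= 0
                                          or self.log_base == 1):
            raise TransitionError(f"invalid log base {self.log_base!r}")

    def to_dict(self) -> dict:
        out: dict = {"min": self.v_min, "max": self.v_max}
        if self.value is not None:
            out["value"] = self.value
        else:
            out["log_base"] = self.log_base
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "RangeRule":
        return cls(v_min=payload["min"], v_max=payload["max"],
                   value=payload.get("value"),
                   log_base=payload.get("log_base"))


@dataclass(frozen=True)
class PivotRule:
    """One Discretize pivot with its below/above replacement values;
    ``None`` means NoChange."""

    pivot: float
    below: float | None = None
    above: float | None = None

    def to_dict(self) -> dict:
        return {"pivot": self.pivot, "below": self.below, "above": self.above}

    @classmethod
    def from_dict(cls, payload: dict) -> "PivotRule":
        return cls(pivot=payload["pivot"], below=payload.get("below"),
                   above=payload.get("above"))


def _check_range(name, lo, hi, size):
    if not (isinstance(lo, (int, np.integer))
            and isinstance(hi, (int, np.integer))):
        raise TransitionError(f"{name} range bounds must be integers")
    if not (0 <= lo < hi <= size):
        raise TransitionError(
            f"{name} range [{lo}, {hi}) invalid for size {size}")
    return int(lo), int(hi)


def extract(space: GenometricSpace, col_range, row_range) -> GenometricSpace:
    """Extract the sub-space at columns ``[C_l, C_r)`` x rows ``[R_u, R_d)``.

    Retained rows and columns keep their ids, labels and metadata; the
    data and metadata of excluded regions/samples are discarded.
    """
    c_l, c_r = _check_range("column", *col_range, space.n_cols)
    r_u, r_d = _check_range("row", *row_range, space.n_rows)
    return space.take(range(r_u, r_d), range(c_l, c_r))


def rewrite(space: GenometricSpace, col_range, row_range,
            rules) -> GenometricSpace:
    """Discretely remap values inside a sub-rectangle.

    Each value falling in a rule's closed interval is replaced by the
    rule's constant or by its logarithm; values in no interval (or outside
    the rectangle) remain intact.  Rule intervals must be pairwise
    disjoint.  Taking the log of a non-positive value yields a missing
    cell and a warning.
    """
    c_l, c_r = _check_range("column", *col_range, space.n_cols)
    r_u, r_d = _check_range("row", *row_range, space.n_rows)
    rules = [r if isinstance(r, RangeRule) else RangeRule.from_dict(r)
             for r in rules]
    ordered = sorted(rules, key=lambda r: (r.v_min, r.v_max))
    for a, b in zip(ordered, ordered[1:]):
        if b.v_min <= a.v_max:  # closed intervals touching at a point overlap
            raise TransitionError(
                f"overlapping rule intervals [{a.v_min}, {a.v_max}] and "
                f"[{b.v_min}, {b.v_max}]")
    values = np.array(space.values, copy=True)
    sub = values[r_u:r_d, c_l:c_r]
    original = sub.copy()
    for rule in rules:
        with np.errstate(invalid="ignore"):
            mask = (original >= rule.v_min) & (original <= rule.v_max)
        if rule.value is not None:
            sub[mask] = rule.value
        else:
            selected = original[mask]
            bad = selected <= 0
            if bad.any():
                warnings.warn(
                    f"log{rule.log_base:g} of {int(bad.sum())} non-positive "
                    "value(s); cells set to missing", stacklevel=2)
            with np.errstate(divide="ignore", invalid="ignore"):
                logged = np.log(selected) / math.log(rule.log_base)
            logged[bad] = np.nan
            sub[mask] = logged
    return space.replace(values=values)


def discretize(space: GenometricSpace, col_range, row_range, rules,
               mode: str = "real") -> GenometricSpace:
    """Contiguously remap values inside a sub-rectangle around pivots.

    ``k`` strictly increasing pivots partition the value line into ``k+1``
    contiguous ranges.  In real mode the ranges around a pivot ``p`` are
    ``(-inf, p]`` and ``(p, +inf)``; in integer mode they are ``(-inf, p]``
    and ``[p+1, +inf)`` (non-integer values strictly between ``p`` and
    ``p+1`` belong to no range and pass through unchanged).  A middle
    range takes its replacement from the lower pivot's ``above`` and the
    upper pivot's ``below``, which must agree when both are given;
    ``None`` (NoChange) leaves the range's values intact.
    """
    c_l, c_r = _check_range("column", *col_range, space.n_cols)
    r_u, r_d = _check_range("row", *row_range, space.n_rows)
    mode = mode.lower()
    if mode not in ("real", "integer"):
        raise TransitionError(f"mode must be 'real' or 'integer', got {mode!r}")
    rules = [r if isinstance(r, PivotRule) else PivotRule.from_dict(r)
             for r in rules]
    if not rules:
        raise TransitionError("at least one pivot rule is required")
    pivots = [r.pivot for r in rules]
    if any(b <= a for a, b in zip(pivots, pivots[1:])):
        raise TransitionError(f"pivots must be strictly increasing: {pivots}")

    # ranges[i] = (lower pivot or None, upper pivot or None, replacement)
    ranges: list[tuple[float | None, float | None, float | None]] = []
    ranges.append((None, rules[0].pivot, rules[0].below))
    for lower, upper in zip(rules, rules[1:]):
        a, b = lower.above, upper.below
        if a is not None and b is not None and a != b:
            raise TransitionError(
                f"conflicting replacements for range between pivots "
                f"{lower.pivot} and {upper.pivot}: above={a} vs below={b}")
        ranges.append((lower.pivot, upper.pivot, a if a is not None else b))
    ranges.append((rules[-1].pivot, None, rules[-1].above))

    values = np.array(space.values, copy=True)
    sub = values[r_u:r_d, c_l:c_r]
    original = sub.copy()
    for lower, upper, replacement in ranges:
        if replacement is None:  # NoChange
            continue
        with np.errstate(invalid="ignore"):
            mask = ~np.isnan(original)
            if lower is not None:
                if mode == "integer":
                    mask &= original >= math.floor(lower) + 1
                else:
                    mask &= original > lower
            if upper is not None:
                mask &= original <= upper
        sub[mask] = replacement
    return space.replace(values=values)


def sort(space: GenometricSpace, axis: str, direction: str,
         keys) -> GenometricSpace:
    """Stable lexicographic multi-key sort of rows or columns.

    Row keys are region attributes — coordinates, reference-region
    attributes, or the per-cell aggregates carried by the space (the
    primary attribute and any auxiliaries), which are reduced to a per-row
    key by the NaN-ignoring row mean.  Column keys are sample metadata
    attributes.  Missing key values sort last regardless of direction;
    when every present value of a key parses as a number the key compares
    numerically, otherwise as text.
    """
    axis = _check_axis(axis)
    direction = str(direction).upper()
    if direction not in ("ASCENDING", "DESCENDING"):
        raise TransitionError(
            f"direction must be ASCENDING or DESCENDING, got {direction!r}")
    keys = list(keys)
    if not keys:
        raise TransitionError("at least one sort key is required")
    n = space.n_rows if axis == "rows" else space.n_cols
    descending = direction == "DESCENDING"

    key_columns = [_key_values(space, axis, key) for key in keys]
    order = list(range(n))
    for raw in reversed(key_columns):
        values = _coerce_key(raw)
        present = [i for i in order if values[i] is not None]
        absent = [i for i in order if values[i] is None]
        present.sort(key=lambda i: values[i], reverse=descending)
        order = present + absent
    if axis == "rows":
        return space.take(order, None)
    return space.take(None, order)


def _key_values(space: GenometricSpace, axis: str, key: str) -> list:
    """Resolve one sort key to a per-element value list (None = missing)."""
    if axis == "columns":
        out = []
        found = False
        for meta in space.col_meta:
            value = None
            for a, v in meta:
                if a == key:
                    value = v
                    found = True
                    break
            out.append(value)
        if not found:
            raise TransitionError(
                f"metadata attribute {key!r} unknown on every column")
        return out

    if key in ("chromosome", "chr", "chrom", "start", "end", "strand"):
        return [_region_field(r, key) for r in space.row_regions]
    matrix = _matrix_for_key(space, key)
    if matrix is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(matrix, axis=1)
        return [None if np.isnan(v) else float(v) for v in means]
    values = [_region_field(r, key) for r in space.row_regions]
    if all(v is None for v in values):
        raise TransitionError(f"row key {key!r} unknown on every row")
    return values


def _matrix_for_key(space: GenometricSpace, key: str):
    """Match a key against the space's primary/auxiliary cell aggregates."""
    if key == space.attribute or key.upper() == space.aggregate:
        return space.values
    if key in space.aux:
        return space.aux[key]
    prefixed = [k for k in space.aux if k.split(":", 1)[0] == key]
    if len(prefixed) == 1:
        return space.aux[prefixed[0]]
    return None


def _coerce_key(raw: list) -> list:
    """Numeric comparison when every present value parses as a number,
    text otherwise."""
    present = [v for v in raw if v is not None]
    if not present:
        return list(raw)
    numeric = []
    for v in present:
        if isinstance(v, (int, float, np.number)) and not isinstance(v, bool):
            numeric.append(float(v))
        else:
            try:
                numeric.append(float(str(v)))
            except ValueError:
                return [None if v is None else str(v) for v in raw]
    it = iter(numeric)
    return [None if v is None else next(it) for v in raw]


def apply_spec(space: GenometricSpace, spec: TransitionSpec):
    """Apply a serialized transition; returns ``(space, dendrogram)``
    where the dendrogram is None for the non-clustering operations."""
    spec = (spec if isinstance(spec, TransitionSpec)
            else TransitionSpec.from_dict(spec))
    p = spec.params
    if spec.op == "EXTRACT":
        return extract(space, p["cols"], p["rows"]), None
    if spec.op == "REWRITE":
        return rewrite(space, p["cols"], p["rows"], p.get("rules", [])), None
    if spec.op == "DISCRETIZE":
        return discretize(space, p["cols"], p["rows"], p["rules"],
                          mode=p.get("mode", "real")), None
    if spec.op == "SORT":
        return sort(space, p["axis"], p["direction"], p["keys"]), None
    if spec.op == "CLUSTER":
        from .clustering import cluster
        reordered, dendrogram = cluster(space, p["axis"], p["linkage"],
                                        p["metric"])
        return reordered, dendrogram
    if spec.op == "BICLUSTER":
        from .clustering import bicluster
        reordered, row_dendro, col_dendro = bicluster(space)
        return reordered, (row_dendro, col_dendro)
    raise TransitionError(f"unknown operation {spec.op!r}")
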