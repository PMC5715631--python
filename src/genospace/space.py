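"""The genometric space: a region-by-sample matrix of aggregated values.

A genometric space is the product of the MAP join: given a *reference*
sample whose regions define the rows and a list of *experiment* samples
defining the columns, cell (i, j) aggregates an attribute over all regions
of experiment j that overlap reference region i.  The classic aggregate
functions COUNT, MIN, MAX, SUM, AVERAGE and MEDIAN are supported; COUNT
needs no attribute and yields 0 for empty overlap bags, every other
aggregate yields a missing value (NaN) there.

Spaces are immutable: every transformation elsewhere in the package
returns a new object, and row/column identifiers survive all of them so a
cell can always be traced back to its source region and sample.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, SpaceError
from .io import GenomicRegion, ParsedSample

AGGREGATES = ("COUNT", "MIN", "MAX", "SUM", "AVERAGE", "MEDIAN")


def overlaps(a: GenomicRegion, b: GenomicRegion) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return (a.chromosome == b.chromosome
            and a.start < b.end and b.start < a.end)


def aggregate_bag(bag: Sequence[float], g: str) -> float:
    """Apply aggregate *g* to a bag of numeric values.

    An empty bag yields 0 under COUNT and NaN (missing) under every other
    aggregate.  MEDIAN of an even-sized bag is the mean of the two middle
    order statistics.
    """
    g = g.upper()
    if g not in AGGREGATES:
        raise SpaceError(f"unknown aggregate {g!r}")
    if g == "COUNT":
        return float(len(bag))
    for v in bag:
        if isinstance(v, bool) or not isinstance(v, (int, float, np.number)):
            raise SpaceError(f"non-numeric value {v!r} in bag for {g}")
    if len(bag) == 0:
        return float("nan")
    arr = np.asarray(bag, dtype=float)
    if g == "MIN":
        return float(arr.min())
    if g == "MAX":
        return float(arr.max())
    if g == "SUM":
        return float(arr.sum())
    if g == "AVERAGE":
        return float(arr.mean())
    return float(np.median(arr))  # MEDIAN


def _frozen(array: np.ndarray) -> np.ndarray:
    array = np.array(array, dtype=float, copy=True)
    array.flags.writeable = False
    return array


class GenometricSpace:
    """Immutable matrix of aggregated values with row/column identities.

    Attributes
    ----------
    values:
        Dense float matrix; NaN marks a missing cell.
    row_ids, col_ids:
        Unique, order-defining identifiers of reference regions / samples.
    row_regions:
        One :class:`GenomicRegion` per row (the reference region record).
    col_meta:
        Per-column metadata multi-map (tuples of attribute/value pairs).
    attribute, aggregate:
        Name of the aggregated attribute (None for COUNT) and the
        aggregate tag that produced ``values``.
    aux:
        Additional per-cell aggregates computed in the same MAP pass,
        keyed ``"<attribute>:<aggregate>"``.
    """

    __slots__ = ("values", "row_ids", "col_ids", "row_regions", "col_meta",
                 "attribute", "aggregate", "aux", "row_label_attr",
                 "col_label_attr")

    def __init__(self, values, row_ids, col_ids, row_regions=None,
                 col_meta=None, attribute=None, aggregate="COUNT", aux=None,
                 row_label_attr=None, col_label_attr=None):
        values = _frozen(values)
        if values.ndim != 2:
            raise SpaceError("values must be a 2-D matrix")
        row_ids = tuple(str(r) for r in row_ids)
        col_ids = tuple(str(c) for c in col_ids)
        if values.shape != (len(row_ids), len(col_ids)):
            raise SpaceError(
                f"shape {values.shape} does not match "
                f"{len(row_ids)} row ids x {len(col_ids)} col ids")
        if len(set(row_ids)) != len(row_ids):
            raise SpaceError("row ids must be unique")
        if len(set(col_ids)) != len(col_ids):
            raise SpaceError("column ids must be unique")
        if row_regions is None:
            row_regions = tuple(
                GenomicRegion("chrU", i * 10, i * 10 + 10,
                              attributes={"name": rid})
                for i, rid in enumerate(row_ids))
        row_regions = tuple(row_regions)
        if len(row_regions) != len(row_ids):
            raise SpaceError("need one region record per row")
        if col_meta is None:
            col_meta = tuple(() for _ in col_ids)
        col_meta = tuple(tuple((str(a), str(v)) for a, v in meta)
                         for meta in col_meta)
        if len(col_meta) != len(col_ids):
            raise SpaceError("need one metadata map per column")
        aux = {str(k): _frozen(v) for k, v in (aux or {}).items()}
        for key, mat in aux.items():
            if mat.shape != values.shape:
                raise SpaceError(f"auxiliary matrix {key!r} has shape "
                                 f"{mat.shape}, expected {values.shape}")
        self.values = values
        self.row_ids = row_ids
        self.col_ids = col_ids
        self.row_regions = row_regions
        self.col_meta = col_meta
        self.attribute = attribute
        self.aggregate = aggregate.upper()
        self.aux = aux
        self.row_label_attr = row_label_attr
        self.col_label_attr = col_label_attr

    # -- basic protocol ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other):
        if not isinstance(other, GenometricSpace):
            return NotImplemented
        return (np.array_equal(self.values, other.values, equal_nan=True)
                and self.row_ids == other.row_ids
                and self.col_ids == other.col_ids
                and self.row_regions == other.row_regions
                and self.col_meta == other.col_meta
                and self.attribute == other.attribute
                and self.aggregate == other.aggregate
                and set(self.aux) == set(other.aux)
                and all(np.array_equal(self.aux[k], other.aux[k],
                                       equal_nan=True) for k in self.aux))

    def __repr__(self):
        what = self.attribute or self.aggregate
        return (f"<GenometricSpace {self.n_rows}x{self.n_cols} "
                f"{what}/{self.aggregate}>")

    def replace(self, **kwargs) -> "GenometricSpace":
        """Return a copy with the given fields substituted."""
        state = {name: getattr(self, name) for name in self.__slots__}
        state.update(kwargs)
        return GenometricSpace(**state)

    def take(self, row_idx=None, col_idx=None) -> "GenometricSpace":
        """Return a new space with rows/columns selected (and reordered)
        by integer index arrays; ``None`` keeps an axis untouched."""
        row_idx = (np.arange(self.n_rows) if row_idx is None
                   else np.asarray(row_idx, dtype=int))
        col_idx = (np.arange(self.n_cols) if col_idx is None
                   else np.asarray(col_idx, dtype=int))
        return self.replace(
            values=self.values[np.ix_(row_idx, col_idx)],
            row_ids=tuple(self.row_ids[i] for i in row_idx),
            col_ids=tuple(self.col_ids[j] for j in col_idx),
            row_regions=tuple(self.row_regions[i] for i in row_idx),
            col_meta=tuple(self.col_meta[j] for j in col_idx),
            aux={k: v[np.ix_(row_idx, col_idx)] for k, v in self.aux.items()},
        )

    # -- labels ------------------------------------------------------------

    def row_labels(self) -> tuple[str, ...]:
        labels = []
        for region in self.row_regions:
            attr = self.row_label_attr
            value = None
            if attr is not None:
                value = _region_field(region, attr)
            elif "name" in region.attributes:
                value = region.attributes["name"]
            if value is None:
                value = f"{region.chromosome}:{region.start}-{region.end}"
            labels.append(str(value))
        return tuple(labels)

    def col_labels(self) -> tuple[str, ...]:
        labels = []
        for cid, meta in zip(self.col_ids, self.col_meta):
            value = None
            if self.col_label_attr is not None:
                for a, v in meta:
                    if a == self.col_label_attr:
                        value = v
                        break
            labels.append(str(value) if value is not None else cid)
        return tuple(labels)

    def relabel(self, axis: str, attribute: str) -> "GenometricSpace":
        """Bind display labels on one axis to *attribute*.

        Values, ids and order are untouched; the attribute must exist for
        at least one element on the axis.
        """
        axis = _check_axis(axis)
        if axis == "rows":
            if not any(_region_field(r, attribute) is not None
                       for r in self.row_regions):
                raise SpaceError(
                    f"attribute {attribute!r} unknown on every row")
            return self.replace(row_label_attr=attribute)
        if not any(a == attribute for meta in self.col_meta for a, _ in meta):
            raise SpaceError(f"attribute {attribute!r} unknown on every column")
        return self.replace(col_label_attr=attribute)

    # -- tabular export ----------------------------------------------------

    def to_table(self) -> str:
        """Render the space as a stable tab-delimited table.

        Layout matches the importable matrix format: ``chr, start, end,
        label`` region columns followed by one column per sample, headed
        by the current column labels.  Missing cells render as ``NA``.
        """
        lines = ["\t".join(["chr", "start", "end", "label"]
                           + list(self.col_labels()))]
        row_labels = self.row_labels()
        for i, region in enumerate(self.row_regions):
            cells = [_format_cell(v) for v in self.values[i]]
            lines.append("\t".join(
                [region.chromosome, str(region.start), str(region.end),
                 row_labels[i]] + cells))
        return "\n".join(lines) + "\n"

    # -- JSON-friendly serialization --------------------------------------

    def to_dict(self) -> dict:
        def matrix(m):
            return [[None if np.isnan(v) else float(v) for v in row]
                    for row in m]

        return {
            "values": matrix(self.values),
            "row_ids": list(self.row_ids),
            "col_ids": list(self.col_ids),
            "rows": [_region_to_dict(r) for r in self.row_regions],
            "col_meta": [[list(p) for p in meta] for meta in self.col_meta],
            "attribute": self.attribute,
            "aggregate": self.aggregate,
            "aux": {k: matrix(v) for k, v in self.aux.items()},
            "row_label_attr": self.row_label_attr,
            "col_label_attr": self.col_label_attr,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GenometricSpace":
        def matrix(m):
            return np.array([[np.nan if v is None else v for v in row]
                             for row in m], dtype=float)

        n_rows = len(payload["row_ids"])
        n_cols = len(payload["col_ids"])
        values = matrix(payload["values"]).reshape(n_rows, n_cols)
        return cls(
            values=values,
            row_ids=payload["row_ids"],
            col_ids=payload["col_ids"],
            row_regions=tuple(_region_from_dict(r) for r in payload["rows"]),
            col_meta=tuple(tuple((a, v) for a, v in meta)
                           for meta in payload["col_meta"]),
            attribute=payload.get("attribute"),
            aggregate=payload.get("aggregate", "COUNT"),
            aux={k: matrix(v).reshape(n_rows, n_cols)
                 for k, v in payload.get("aux", {}).items()},
            row_label_attr=payload.get("row_label_attr"),
            col_label_attr=payload.get("col_label_attr"),
        )

    @classmethod
    def from_matrix(cls, values, row_ids=None, col_ids=None, **kwargs
                    ) -> "GenometricSpace":
        """Wrap a plain matrix (mainly for analyses and tests)."""
        values = np.asarray(values, dtype=float)
        if row_ids is None:
            row_ids = [f"R{i}" for i in range(values.shape[0])]
        if col_ids is None:
            col_ids = [f"S{j}" for j in range(values.shape[1])]
        return cls(values, row_ids, col_ids, **kwargs)


def _check_axis(axis: str) -> str:
    axis = str(axis).lower()
    if axis in ("rows", "r", "row"):
        return "rows"
    if axis in ("columns", "c", "cols", "column"):
        return "columns"
    raise SpaceError(f"axis must be 'rows' or 'columns', got {axis!r}")


def _region_field(region: GenomicRegion, attribute: str):
    if attribute == "chromosome" or attribute in ("chr", "chrom"):
        return region.chromosome
    if attribute == "start":
        return region.start
    if attribute == "end":
        return region.end
    if attribute == "strand":
        return region.strand
    return region.attributes.get(attribute)


def _format_cell(value: float) -> str:
    if np.isnan(value):
        return "NA"
    return f"{value:.10g}"


def _region_to_dict(region: GenomicRegion) -> dict:
    return {"chromosome": region.chromosome, "start": region.start,
            "end": region.end, "strand": region.strand,
            "attributes": list(region.attributes.items())}


def _region_from_dict(payload: dict) -> GenomicRegion:
    return GenomicRegion(payload["chromosome"], payload["start"],
                         payload["end"], payload.get("strand", "unknown"),
                         dict(payload.get("attributes", [])))


# -- the MAP join ----------------------------------------------------------

def map_samples(reference: ParsedSample,
                experiments: Sequence[ParsedSample],
                attribute: str | None = None,
                aggregate: str = "COUNT",
                extra: Iterable[tuple[str | None, str]] = (),
                ) -> GenometricSpace:
    """Join experiment samples onto a reference region set.

    Produces one row per reference region (in file order) and one column
    per experiment (in the given order).  Cell (i, j) aggregates
    *attribute* over the regions of experiment j overlapping reference
    region i.  *extra* lists additional ``(attribute, aggregate)`` pairs
    computed in the same pass and stored as auxiliary per-cell matrices,
    so that, e.g., an aggregated p-value can ride along with a count.

    The join sorts each experiment per chromosome and prunes candidates
    with a binary search on region starts, so it does not degenerate to
    the quadratic all-pairs scan.
    """
    if not reference.regions:
        raise SpaceError("reference sample has no regions")
    requests = [(attribute, aggregate.upper())]
    requests += [(a, g.upper()) for a, g in extra]
    for attr, g in requests:
        if g not in AGGREGATES:
            raise SpaceError(f"unknown aggregate {g!r}")
        if g != "COUNT" and attr is None:
            raise SpaceError(f"aggregate {g} requires an attribute name")

    needed_attrs = sorted({a for a, g in requests if g != "COUNT"})
    indexes = []
    for j, exp in enumerate(experiments):
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for idx, region in enumerate(exp.regions):
            by_chrom.setdefault(region.chromosome, []).append(
                (region.start, region.end, idx))
        chrom_index = {}
        for chrom, triples in by_chrom.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            attr_values = {}
            for attr in needed_attrs:
                vals = []
                for start, end, idx in triples:
                    v = exp.regions[idx].attributes.get(attr)
                    if isinstance(v, bool) or not isinstance(
                            v, (int, float, np.number)):
                        raise SpaceError(
                            f"attribute {attr!r} missing or non-numeric in "
                            f"sample {exp.sample_id!r}, region {idx}")
                    vals.append(float(v))
                attr_values[attr] = np.array(vals, dtype=float)
            chrom_index[chrom] = (starts, ends, attr_values)
        indexes.append(chrom_index)

    ref_chroms = {r.chromosome for r in reference.regions}
    exp_chroms = {c for chrom_index in indexes for c in chrom_index}
    if experiments and exp_chroms and not (ref_chroms & exp_chroms):
        warnings.warn("reference and experiments share no chromosome "
                      "names; every cell will be empty", stacklevel=2)

    n_rows, n_cols = len(reference.regions), len(experiments)
    matrices = {key: np.full((n_rows, n_cols), np.nan)
                for key in range(len(requests))}
    for j, chrom_index in enumerate(indexes):
        for i, ref_region in enumerate(reference.regions):
            entry = chrom_index.get(ref_region.chromosome)
            if entry is None:
                hits = None
            else:
                starts, ends, attr_values = entry
                hi = int(np.searchsorted(starts, ref_region.end, side="left"))
                mask = ends[:hi] > ref_region.start
                hits = (mask, attr_values)
            for key, (attr, g) in enumerate(requests):
                if hits is None:
                    bag = ()
                elif g == "COUNT":
                    bag = [0.0] * int(hits[0].sum())
                else:
                    bag = hits[1][attr][: len(hits[0])][hits[0]].tolist()
                matrices[key][i, j] = aggregate_bag(bag, g)

    aux = {f"{a if a is not None else 'COUNT'}:{g}": matrices[key]
           for key, (a, g) in enumerate(requests) if key != 0}
    return GenometricSpace(
        values=matrices[0],
        row_ids=[f"R{i}" for i in range(n_rows)],
        col_ids=[exp.sample_id for exp in experiments],
        row_regions=reference.regions,
        col_meta=[exp.metadata for exp in experiments],
        attribute=attribute,
        aggregate=aggregate,
        aux=aux,
    )


def read_matrix(path) -> GenometricSpace:
    """Import a pre-built matrix laid out as region columns (chr, start,
    end and optionally label) followed by one column per sample — the
    layout produced by :meth:`GenometricSpace.to_table` and by GMQL MAP
    exports."""
    with open(path) as handle:
        header_line = handle.readline().rstrip("\n")
        if not header_line:
            raise FormatError("empty matrix file", path=path)
        header = header_line.split("\t")
        lowered = [h.strip().lower() for h in header]
        n_lead = 0
        for name in lowered:
            if name in _MATRIX_LEAD_COLUMNS:
                n_lead += 1
            else:
                break
        if n_lead < 3:
            raise FormatError(
                "matrix header must start with chr/start/end columns",
                path=path, line=1)
        has_label = "label" in lowered[:n_lead]
        sample_names = header[n_lead:]
        regions, rows = [], []
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"expected {len(header)} columns, got {len(fields)}",
                    path=path, line=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError("non-integer coordinates", path=path,
                                  line=lineno)
            attrs = {"name": fields[3]} if has_label else {}
            regions.append(GenomicRegion(fields[0], start, end,
                                         attributes=attrs))
            rows.append([_parse_cell(tok) for tok in fields[n_lead:]])
        if not regions:
            raise FormatError("matrix file has no data rows", path=path)
    values = np.array(rows, dtype=float)
    col_ids = _dedupe(sample_names)
    return GenometricSpace(values=values,
                           row_ids=[f"R{i}" for i in range(len(regions))],
                           col_ids=col_ids, row_regions=regions,
                           aggregate="COUNT", attribute=None)


_MATRIX_LEAD_COLUMNS = _CHROM = {"chr", "chrom", "chromosome", "start",
                                 "end", "stop", "label"}


def _parse_cell(token: str) -> float:
    token = token.strip()
    if token in ("", "NA", "NaN", "nan", "."):
        return float("nan")
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"non-numeric matrix cell {token!r}")


def _dedupe(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out
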