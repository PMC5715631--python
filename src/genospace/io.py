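"""Readers and writers for genomic region files and per-sample metadata.

Supported region formats are BED (3+ columns), BroadPeak, NarrowPeak, GTF
and a generic tab-delimited layout with a header row.  Everything is
normalized on read to a single internal coordinate convention: 0-based,
half-open ``[start, end)``.  GTF, which is 1-based closed on disk, is
shifted by one on read and shifted back on write; the BED family passes
through unchanged.

Metadata travel as sibling files named ``<region file name>.meta`` holding
tab-delimited attribute/value pairs.  Duplicate attribute names are legal
and retained in file order (a multi-map), because downstream pattern
aggregation counts occurrences of attribute-value pairs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

from .errors import FormatError

FORMATS = ("BED", "BROADPEAK", "NARROWPEAK", "GTF", "GENERIC_TSV")

#: positional attribute names after chrom/start/end, per UCSC definitions
_BED_FIELDS = ("name", "score", "strand", "thickStart", "thickEnd",
               "itemRgb", "blockCount", "blockSizes", "blockStarts")
_BROADPEAK_FIELDS = ("name", "score", "strand", "signalValue", "pValue",
                     "qValue")
_NARROWPEAK_FIELDS = _BROADPEAK_FIELDS + ("peak",)

_SUFFIX_FORMAT = {
    ".bed": "BED",
    ".broadpeak": "BROADPEAK",
    ".narrowpeak": "NARROWPEAK",
    ".gtf": "GTF",
    ".tsv": "GENERIC_TSV",
    ".txt": "GENERIC_TSV",
}

_CHROM_ALIASES = {"chr", "chrom", "chromosome", "seqname", "seqid"}
_START_ALIASES = {"start", "chromstart"}
_END_ALIASES = {"end", "stop", "chromend"}


@dataclass(frozen=True)
class GenomicRegion:
    """One genomic interval with optional named attributes.

    Coordinates follow the internal convention (0-based, half-open).
    ``strand`` is one of ``+``, ``-`` or ``unknown``; it is parsed but
    ignored by every downstream operation.  Attribute values are numbers
    or text; ``None`` marks a value that was ``.`` in the source file.
    """

    chromosome: str
    start: int
    end: int
    strand: str = "unknown"
    attributes: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise FormatError(f"coordinates must be integers, got "
                              f"{self.start!r}/{self.end!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) on "
                f"{self.chromosome}: need 0 <= start < end")
        if self.strand not in ("+", "-", "unknown"):
            raise FormatError(f"invalid strand {self.strand!r}")
        object.__setattr__(self, "attributes",
                           MappingProxyType(dict(self.attributes)))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ParsedSample:
    """A sample's regions plus its metadata attribute-value pairs.

    ``metadata`` is an ordered multi-map represented as a tuple of
    ``(attribute, value)`` pairs; duplicates are retained in file order.
    """

    sample_id: str
    name: str
    regions: tuple[GenomicRegion, ...]
    metadata: tuple[tuple[str, str], ...] = ()
    source_format: str = "GENERIC_TSV"

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "metadata",
                           tuple((str(a), str(v)) for a, v in self.metadata))

    def metadata_get(self, attribute: str, default=None):
        """First value bound to *attribute*, or *default*."""
        for a, v in self.metadata:
            if a == attribute:
                return v
        return default


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_value(token: str):
    """Numeric if it parses as a number, ``None`` for '.', else text."""
    if token == ".":
        return None
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        return token


def _format_value(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:.10g}"
    return str(value)


def _parse_strand(token) -> str:
    return token if token in ("+", "-") else "unknown"


def infer_format(path) -> str:
    suffix = Path(path).name.lower()
    if suffix.endswith(".gz"):
        suffix = suffix[:-3]
    ext = "." + suffix.rsplit(".", 1)[-1] if "." in suffix else ""
    try:
        return _SUFFIX_FORMAT[ext]
    except KeyError:
        raise FormatError(f"cannot infer format from file name", path=path)


def read_regions(path, format: str | None = None,
                 header: bool | None = None) -> ParsedSample:
    """Read a region file into a :class:`ParsedSample`.

    Parameters
    ----------
    path:
        File to read; ``.gz`` suffixed files are decompressed on the fly.
    format:
        One of :data:`FORMATS`; inferred from the file extension if omitted.
    header:
        Whether the first non-comment line is a header.  Defaults to True
        for GENERIC_TSV (where it is required) and False otherwise.
    """
    path = Path(path)
    fmt = (format or infer_format(path)).upper()
    if fmt not in FORMATS:
        raise FormatError(f"unknown format tag {fmt!r}", path=path)
    if header is None:
        header = fmt == "GENERIC_TSV"

    regions: list[GenomicRegion] = []
    with _open_text(path) as handle:
        if fmt == "GENERIC_TSV":
            regions = _read_generic(handle, path)
        else:
            skipped_header = not header
            for lineno, raw in enumerate(handle, start=1):
                line = raw.rstrip("\n").rstrip("\r")
                if not line.strip():
                    continue
                if line.startswith(("#", "track", "browser")):
                    continue
                if not skipped_header:
                    skipped_header = True
                    continue
                try:
                    if fmt == "GTF":
                        regions.append(_parse_gtf_line(line))
                    else:
                        regions.append(_parse_bed_line(line, fmt))
                except FormatError as exc:
                    raise FormatError(str(exc), path=path, line=lineno)
    name = path.name
    for suffix in (".gz",):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    stem = name.rsplit(".", 1)[0] if "." in name else name
    return ParsedSample(sample_id=path.name, name=stem,
                        regions=tuple(regions), source_format=fmt)


def _parse_bed_line(line: str, fmt: str) -> GenomicRegion:
    fields = line.split()
    if len(fields) < 3:
        raise FormatError(f"expected at least 3 columns, got {len(fields)}")
    names = {"BED": _BED_FIELDS, "BROADPEAK": _BROADPEAK_FIELDS,
             "NARROWPEAK": _NARROWPEAK_FIELDS}[fmt]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise FormatError(f"non-integer coordinates {fields[1]!r}/{fields[2]!r}")
    attrs: dict[str, object] = {}
    strand = "unknown"
    for name, token in zip(names, fields[3:]):
        if name == "strand":
            strand = _parse_strand(token)
        else:
            attrs[name] = _parse_value(token)
    for i, token in enumerate(fields[3 + len(names):]):
        attrs[f"col{4 + len(names) + i}"] = _parse_value(token)
    return GenomicRegion(fields[0].strip(), start, end, strand, attrs)


def _parse_gtf_line(line: str) -> GenomicRegion:
    fields = line.split("\t")
    if len(fields) < 9:
        fields = line.split(None, 8)
    if len(fields) < 8:
        raise FormatError(f"expected 9 GTF fields, got {len(fields)}")
    seqname, source, feature, start_s, end_s, score, strand, frame = fields[:8]
    group = fields[8] if len(fields) > 8 else ""
    try:
        start, end = int(start_s) - 1, int(end_s)  # 1-based closed -> half-open
    except ValueError:
        raise FormatError(f"non-integer coordinates {start_s!r}/{end_s!r}")
    attrs: dict[str, object] = {
        "source": _parse_value(source),
        "feature": _parse_value(feature),
        "score": _parse_value(score),
        "frame": _parse_value(frame),
    }
    for segment in group.split(";"):
        segment = segment.strip()
        if not segment:
            continue
        key, _, value = segment.partition(" ")
        attrs[key] = _parse_value(value.strip().strip('"'))
    return GenomicRegion(seqname.strip(), start, end, _parse_strand(strand),
                         attrs)


def _read_generic(handle, path) -> list[GenomicRegion]:
    header_fields = None
    regions: list[GenomicRegion] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if header_fields is None:
            header_fields = [f.strip() for f in fields]
            lowered = [f.lower() for f in header_fields]
            chrom_i = start_i = end_i = strand_i = None
            for i, name in enumerate(lowered):
                if name in _CHROM_ALIASES and chrom_i is None:
                    chrom_i = i
                elif name in _START_ALIASES and start_i is None:
                    start_i = i
                elif name in _END_ALIASES and end_i is None:
                    end_i = i
                elif name == "strand" and strand_i is None:
                    strand_i = i
            if chrom_i is None or start_i is None or end_i is None:
                raise FormatError(
                    "header must name chromosome/start/end columns "
                    f"(got {header_fields})", path=path, line=lineno)
            special = {chrom_i, start_i, end_i}
            if strand_i is not None:
                special.add(strand_i)
            attr_cols = [(i, header_fields[i])
                         for i in range(len(header_fields)) if i not in special]
            layout = (chrom_i, start_i, end_i, strand_i, attr_cols)
            continue
        chrom_i, start_i, end_i, strand_i, attr_cols = layout
        if len(fields) != len(header_fields):
            raise FormatError(
                f"expected {len(header_fields)} columns, got {len(fields)}",
                path=path, line=lineno)
        try:
            start, end = int(fields[start_i]), int(fields[end_i])
        except ValueError:
            raise FormatError(
                f"non-integer coordinates "
                f"{fields[start_i]!r}/{fields[end_i]!r}",
                path=path, line=lineno)
        strand = (_parse_strand(fields[strand_i])
                  if strand_i is not None else "unknown")
        attrs = {name: _parse_value(fields[i]) for i, name in attr_cols}
        try:
            regions.append(GenomicRegion(fields[chrom_i].strip(), start, end,
                                         strand, attrs))
        except FormatError as exc:
            raise FormatError(str(exc), path=path, line=lineno)
    if header_fields is None:
        raise FormatError("empty GENERIC_TSV file (header required)",
                          path=path)
    return regions


def read_metadata(path) -> tuple[tuple[str, str], ...]:
    """Read a two-column tab-delimited attribute/value file.

    Returns pairs in file order; duplicate attributes are retained.
    """
    pairs: list[tuple[str, str]] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"expected 2 tab-separated fields, got {len(fields)}",
                    path=path, line=lineno)
            pairs.append((fields[0], fields[1]))
    return tuple(pairs)


def attach_metadata(sample: ParsedSample, search_dir) -> ParsedSample:
    """Attach ``<sample file name>.meta`` from *search_dir* if present.

    Returns the sample unchanged when no sibling metadata file exists.
    """
    meta_path = Path(search_dir) / f"{sample.sample_id}.meta"
    if not meta_path.exists():
        return sample
    return replace(sample, metadata=read_metadata(meta_path))


def write_metadata(pairs, path) -> None:
    with open(path, "wt") as handle:
        for attribute, value in pairs:
            handle.write(f"{attribute}\t{value}\n")


def write_regions(sample: ParsedSample, path, format: str | None = None
                  ) -> None:
    """Write a sample's regions to *path* in the given format.

    The writer is the exact inverse of :func:`read_regions`: coordinates
    and attributes shared by the format round-trip unchanged (GTF gets its
    1-based shift back).  Attributes a positional format cannot carry are
    appended as extra trailing columns for BED, and dropped for the peak
    formats.
    """
    fmt = (format or sample.source_format or infer_format(path)).upper()
    if fmt not in FORMATS:
        raise FormatError(f"unknown format tag {fmt!r}", path=path)
    with open(path, "wt") as handle:
        if fmt == "GENERIC_TSV":
            _write_generic(sample, handle)
            return
        for region in sample.regions:
            if fmt == "GTF":
                handle.write(_format_gtf_line(region) + "\n")
            else:
                handle.write(_format_bed_line(region, fmt) + "\n")


def _format_bed_line(region: GenomicRegion, fmt: str) -> str:
    names = {"BED": _BED_FIELDS, "BROADPEAK": _BROADPEAK_FIELDS,
             "NARROWPEAK": _NARROWPEAK_FIELDS}[fmt]
    out = [region.chromosome, str(region.start), str(region.end)]
    attrs = dict(region.attributes)
    strand_token = region.strand if region.strand != "unknown" else "."
    columns = []
    for name in names:
        if name == "strand":
            columns.append(strand_token)
        else:
            columns.append(_format_value(attrs.pop(name, None)))
    if fmt == "BED":
        for name in attrs:  # insertion order
            columns.append(_format_value(attrs[name]))
    # drop trailing all-missing columns so a bare 3-column BED stays bare
    while columns and columns[-1] == ".":
        columns.pop()
    return "\t".join(out + columns)


def _format_gtf_line(region: GenomicRegion) -> str:
    attrs = dict(region.attributes)
    source = _format_value(attrs.pop("source", None))
    feature = _format_value(attrs.pop("feature", None))
    score = _format_value(attrs.pop("score", None))
    frame = _format_value(attrs.pop("frame", None))
    strand = region.strand if region.strand != "unknown" else "."
    group = " ".join(f'{k} "{_format_value(v)}";' for k, v in attrs.items())
    return "\t".join([region.chromosome, source, feature,
                      str(region.start + 1), str(region.end), score, strand,
                      frame, group])


def _write_generic(sample: ParsedSample, handle) -> None:
    attr_names: list[str] = []
    for region in sample.regions:
        for name in region.attributes:
            if name not in attr_names:
                attr_names.append(name)
    handle.write("\t".join(["chr", "start", "end", "strand"] + attr_names)
                 + "\n")
    for region in sample.regions:
        strand = region.strand if region.strand != "unknown" else "."
        row = [region.chromosome, str(region.start), str(region.end), strand]
        row += [_format_value(region.attributes.get(n)) for n in attr_names]
        handle.write("\t".join(row) + "\n")
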