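"""Seeded synthetic datasets with planted block structure.

The generator emulates the shape of a ChIP-seq mapping study: a reference
BED of gene-like regions, several BroadPeak experiment samples whose
called peaks overlap those regions, and per-sample ``.meta`` files with
attribute/value metadata (Treatment, Dose, Duration, Antibody target).
Samples fall into column clusters and reference regions into row
clusters; a sample in column cluster c carries strongly significant peaks
over the regions of its associated row cluster and only weak background
peaks elsewhere, so mapping a fixture yields a matrix with planted
block structure recoverable by clustering.

Peak significances are emitted in -10*log10(p) form by default, the
convention for called-peak p-value columns (a raw-scale toggle exists).
All outputs are fully determined by the seed, byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .space import GenometricSpace

#: default metadata vocabulary: attribute -> candidate values
DEFAULT_VOCABULARY = {
    "Treatment": ("Dexamethasone", "Ethanol", "None"),
    "Dose": ("500 pM", "5 nM", "50 nM", "100 nM", "0.02 %", "None"),
    "Duration": ("30 m", "1 h", "2 h", "5 h", "None"),
    "Antibody target": ("ATF3", "BCL3", "CTCF", "EP300", "GABPA", "JUNB",
                        "JUND", "NR3C1", "POLR2A", "REST", "SIN3A", "SIX5",
                        "TAF1", "TCF12", "USF1"),
}


@dataclass
class FixtureConfig:
    """Everything that determines a synthetic dataset.

    The defaults mirror a 171-gene x 33-sample ChIP-seq mapping study:
    three treatment groups of 16/13/4 samples, two planted row clusters
    of 72 and 99 reference regions, strong block enrichment around
    -10*log10(p) = 80 over a weak background around 15, and one cell in
    ten left without any overlapping peak.
    """

    n_reference_regions: int = 171
    n_samples: int = 33
    chromosomes: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4", "chr5")
    min_region_length: int = 1000
    max_region_length: int = 10000
    n_row_clusters: int = 2
    n_col_clusters: int = 3
    row_cluster_sizes: tuple[int, ...] | None = (72, 99)
    col_cluster_sizes: tuple[int, ...] | None = (16, 13, 4)
    signal_level: float = 80.0
    background_level: float = 15.0
    noise_sd: float = 5.0
    empty_fraction: float = 0.10
    pvalue_log_format: bool = True
    metadata_vocabulary: dict = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_VOCABULARY.items()})
    seed: int = 0

    def __post_init__(self):
        for name in ("n_reference_regions", "n_samples", "n_row_clusters",
                     "n_col_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.empty_fraction < 1.0):
            raise ValueError("empty_fraction must be in [0, 1)")
        for sizes, total, what in (
                (self.row_cluster_sizes, self.n_reference_regions, "row"),
                (self.col_cluster_sizes, self.n_samples, "column")):
            if sizes is not None and sum(sizes) != total:
                raise ValueError(f"{what} cluster sizes {sizes} do not sum "
                                 f"to {total}")


def _split_sizes(total: int, parts: int, sizes) -> list[int]:
    if sizes is not None:
        return list(sizes)
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _study_metadata(config: FixtureConfig, col_clusters: list[int],
                    rng) -> list[list[tuple[str, str]]]:
    """Per-sample metadata: treatment group shared within a column
    cluster, antibody target drawn per sample."""
    vocab = config.metadata_vocabulary
    treatments = list(vocab.get("Treatment", ["group"]))
    doses = list(vocab.get("Dose", ["None"]))
    durations = list(vocab.get("Duration", ["None"]))
    targets = list(vocab.get("Antibody target", ["X"]))
    metadata = []
    for j, c in enumerate(col_clusters):
        treatment = treatments[c % len(treatments)]
        dose = doses[c % len(doses)]
        duration = durations[c % len(durations)]
        target = targets[int(rng.integers(len(targets)))]
        metadata.append([
            ("Treatment", treatment),
            ("Dose", dose),
            ("Duration", duration),
            ("Antibody target", target),
        ])
    return metadata


def generate_fixture(config: FixtureConfig, out_dir) -> dict:
    """Write a reference BED, BroadPeak samples and ``.meta`` files.

    Returns (and writes as ``manifest.json``) a manifest recording every
    file plus the planted ground-truth row/column memberships.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    row_sizes = _split_sizes(config.n_reference_regions,
                             config.n_row_clusters, config.row_cluster_sizes)
    col_sizes = _split_sizes(config.n_samples, config.n_col_clusters,
                             config.col_cluster_sizes)
    row_clusters = [c for c, size in enumerate(row_sizes) for _ in range(size)]
    # samples arrive in shuffled order, as real collections do; sorting by
    # a metadata key is what makes the treatment groups contiguous again
    col_assignment = np.repeat(np.arange(len(col_sizes)), col_sizes)
    rng.shuffle(col_assignment)
    col_clusters = [int(c) for c in col_assignment]

    # reference regions: non-overlapping per chromosome, round-robin
    cursors = {chrom: 10_000 for chrom in config.chromosomes}
    regions = []  # (chrom, start, end, name)
    for i in range(config.n_reference_regions):
        chrom = config.chromosomes[i % len(config.chromosomes)]
        gap = int(rng.integers(500, 5000))
        length = int(rng.integers(config.min_region_length,
                                  config.max_region_length + 1))
        start = cursors[chrom] + gap
        cursors[chrom] = start + length
        regions.append((chrom, start, start + length, f"gene{i:03d}"))

    reference_name = "reference.bed"
    with open(out_dir / reference_name, "wt") as handle:
        for chrom, start, end, name in regions:
            handle.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t+\n")

    metadata = _study_metadata(config, col_clusters, rng)

    samples = []
    for j in range(config.n_samples):
        c = col_clusters[j]
        enriched_cluster = c % config.n_row_clusters
        file_name = f"S{j:02d}.broadpeak"
        lines = []
        peak_no = 0
        for i, (chrom, start, end, _) in enumerate(regions):
            enriched = row_clusters[i] == enriched_cluster
            if not enriched and rng.random() < config.empty_fraction:
                continue
            level = (config.signal_level if enriched
                     else config.background_level)
            n_peaks = 1 + int(enriched and rng.random() < 0.5)
            for _ in range(n_peaks):
                length = end - start
                p_start = start + int(rng.integers(0, max(1, length // 2)))
                p_len = int(rng.integers(200, max(201, length)))
                p_end = min(end + 500, p_start + p_len)
                value = max(1.0, float(rng.normal(level, config.noise_sd)))
                p_field = (value if config.pvalue_log_format
                           else 10.0 ** (-value / 10.0))
                signal = value / 10.0
                q_field = max(0.0, value - 5.0)
                score = min(1000, int(value * 10))
                lines.append(
                    f"{chrom}\t{p_start}\t{p_end}\tpeak{peak_no:05d}\t"
                    f"{score}\t.\t{signal:.4f}\t{p_field:.4g}\t"
                    f"{q_field:.4f}")
                peak_no += 1
        with open(out_dir / file_name, "wt") as handle:
            handle.write("\n".join(lines) + "\n")
        with open(out_dir / f"{file_name}.meta", "wt") as handle:
            for attribute, value in metadata[j]:
                handle.write(f"{attribute}\t{value}\n")
        samples.append({"file": file_name, "sample_id": file_name,
                        "col_cluster": c,
                        "metadata": [list(p) for p in metadata[j]]})

    manifest = {
        "reference": reference_name,
        "samples": samples,
        "row_clusters": row_clusters,
        "col_clusters": col_clusters,
        "config": _config_dict(config),
    }
    with open(out_dir / "manifest.json", "wt") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return manifest


def _config_dict(config: FixtureConfig) -> dict:
    out = asdict(config)
    out["chromosomes"] = list(config.chromosomes)
    for key in ("row_cluster_sizes", "col_cluster_sizes"):
        if out[key] is not None:
            out[key] = list(out[key])
    return out


def blob_space(n_clusters: int, points_per_cluster: int = 8,
               n_features: int = 4, separation: float = 50.0,
               spread: float = 1.0, seed: int = 0
               ) -> tuple[GenometricSpace, list[int]]:
    """Rows drawn from well-separated, mutually equidistant Gaussian blobs.

    Cluster centers sit at the vertices of a randomly oriented regular
    simplex, so every pairwise center distance equals *separation*; each
    point is its center plus isotropic Gaussian noise with standard
    deviation *spread*.  Returns the space (blob rows in cluster order)
    and the ground-truth row labels.  The feature dimension is raised to
    ``n_clusters`` when needed to host the simplex.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    n_features = max(n_features, n_clusters)
    # regular simplex with unit pairwise distances, centered at the origin
    simplex = np.eye(n_clusters) / np.sqrt(2.0)
    simplex -= simplex.mean(axis=0)
    centers = np.zeros((n_clusters, n_features))
    centers[:, :n_clusters] = simplex * separation
    centers = centers @ stats.ortho_group.rvs(n_features, random_state=rng)
    rows, labels = [], []
    for g in range(n_clusters):
        pts = centers[g] + rng.normal(0.0, spread,
                                      size=(points_per_cluster, n_features))
        rows.append(pts)
        labels.extend([g] * points_per_cluster)
    X = np.vstack(rows)
    space = GenometricSpace.from_matrix(
        X, row_ids=[f"P{i}" for i in range(X.shape[0])])
    return space, labels
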