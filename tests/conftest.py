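import numpy as np
import pytest

from genospace import (FixtureConfig, GenomicRegion, GenometricSpace,
                       ParsedSample, generate_fixture)


def random_regions(rng, n, chroms=("chr1", "chr2"), span=2000,
                   attrs=("score", "pValue")):
    regions = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 120))
        attributes = {"name": f"r{i}"}
        for attr in attrs:
            attributes[attr] = round(float(rng.uniform(0.5, 100.0)), 4)
        regions.append(GenomicRegion(
            chromosome=str(rng.choice(list(chroms))), start=start,
            end=start + length,
            strand=str(rng.choice(["+", "-", "unknown"])),
            attributes=attributes))
    return tuple(regions)


def random_sample(rng, sample_id, n_regions, **kwargs) -> ParsedSample:
    return ParsedSample(sample_id=sample_id, name=sample_id,
                        regions=random_regions(rng, n_regions, **kwargs),
                        metadata=(("Treatment", f"T{rng.integers(3)}"),
                                  ("Antibody target", f"AB{rng.integers(4)}")),
                        source_format="GENERIC_TSV")


def random_space(rng, n_rows=6, n_cols=4, missing=0.0) -> GenometricSpace:
    values = rng.uniform(-5, 50, size=(n_rows, n_cols))
    if missing:
        mask = rng.random(values.shape) < missing
        values[mask] = np.nan
    col_meta = tuple(
        (("Treatment", f"T{j % 2}"), ("Antibody target", f"AB{j % 3}"))
        for j in range(n_cols))
    return GenometricSpace.from_matrix(values, col_meta=col_meta,
                                       attribute="pValue",
                                       aggregate="AVERAGE")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A compact planted dataset: 30 regions x 9 samples, 3 column groups."""
    out = tmp_path_factory.mktemp("fixture")
    config = FixtureConfig(
        n_reference_regions=30, n_samples=9, n_row_clusters=3,
        n_col_clusters=3, row_cluster_sizes=None, col_cluster_sizes=None,
        empty_fraction=0.1, seed=7)
    manifest = generate_fixture(config, out)
    return out, manifest
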