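# Methods

This note records the model conventions, parameter defaults and numerical
choices behind genospace, and what the synthetic fixtures do and do not
emulate.

## Coordinates, formats and metadata

All regions are normalized on read to 0-based, half-open `[start, end)`
intervals; GTF (1-based, closed) is shifted by one on read and back on
write, the BED family passes through.  Zero-length regions are rejected.
Overlap is strict half-open intersection — at least one shared base, with
no minimum-overlap fraction.  Chromosome names are compared as exact
strings after whitespace trimming; no `chr`-prefix normalization is
attempted, but a warning is emitted when reference and experiments share
no chromosome name at all.  Strand is parsed and carried but ignored by
every analysis.  Attribute values that parse as numbers are stored as
numbers, `.` is stored as missing; this includes GTF `score`/`frame`.
Metadata files are two-column TSVs; duplicate attribute names are legal
and kept in order (a multi-map), because pattern aggregation counts
attribute-value pair occurrences.

## The MAP join

One row per reference region in file order, one column per experiment in
input order.  The join sorts each experiment per chromosome and prunes
candidate overlaps by binary search on region starts, avoiding the
quadratic all-pairs scan.  Empty overlap bags give 0 under COUNT and NaN
under the value aggregates — inventing a 0 p-value for an empty cell
would be wrong; the CLI `--fill` flag exists for users who want a
constant instead.  MEDIAN of an even bag is the mean of the two middle
order statistics.  A region overlapping a reference region counts once,
however many fragments of it overlap.  Duplicate reference regions each
produce their own row.

## Transitions

Index ranges are `[lower, upper)` and refer to the current (possibly
sorted) order of the space.  Rewrite intervals are closed on both ends
and must be pairwise disjoint; the log option applies the logarithm to
the original value, and log of a non-positive value produces a missing
cell plus a warning.  Discretize has an explicit `real`/`integer` domain
mode (default `real`): around a pivot *p* the ranges are `(-inf, p]` /
`(p, +inf)` in real mode and `(-inf, p]` / `[p+1, +inf)` in integer mode,
where non-integer values strictly between *p* and *p*+1 belong to no
range and pass through.  A middle range's replacement comes from the
lower pivot's `above` and the upper pivot's `below`, which must agree
when both are given.

Sort is a stable lexicographic multi-key sort with one direction for all
keys.  Row keys resolve, in order, to coordinates/strand, then to the
space's per-cell aggregates (primary attribute or auxiliaries, reduced to
a per-row key by the NaN-ignoring row mean), then to reference-region
attributes; column keys are sample metadata.  Missing keys sort last
regardless of direction; a key whose present values all parse as numbers
compares numerically, otherwise as text; ties keep the original order.

Every transition is described by a JSON `TransitionSpec`, and applying
the same spec to the same space is bitwise reproducible — the property
the state tree's replay reconstruction relies on.

## State tree and caching

The root state is cached permanently; at most `capacity` (default 10)
non-root states hold their matrix at any time, managed least-recently
used.  Recency updates on both creation and reads, since exploration
revisits states.  The root does not count against the capacity.
Reconstruction walks to the nearest cached ancestor and replays specs
downward, caching only the requested node to avoid thrashing.
Dendrograms are never evicted.  Bi-cluster nodes are terminal leaves.
Sessions persist as a JSON manifest holding the capacity, the spec tree
and a full-fidelity serialization of the root space (a sibling
`.root.tsv` is written for human inspection); non-root spaces are
reconstructed lazily after loading.

## Clustering

Agglomerative clustering with single, complete and unweighted-average
(UPGMA — "average" is taken as the unweighted mean over all inter-cluster
pairs, not WPGMA) linkage, maintained via the Lance-Williams recurrences;
the test suite checks the merge traces against a from-scratch oracle.
Ties break toward the lexicographically smallest pair of cluster indices,
making results platform-independent.  Missing cells are imputed as 0 for
distance computation only, with a warning.

Metrics: Euclidean, Manhattan, Chebyshev; Canberra with 0/0 terms counted
as 0; Pearson distance is 1 − r (anticorrelated vectors are maximally
distant, not similar); the earth mover's distance is specialized to 1-D
vectors read as signatures over ordered bins with unit ground distance,
i.e. the summed absolute prefix differences.  Pearson distance errors on
zero-variance vectors.

Newick export renders the ultrametric tree (a merge at height *h* sits at
depth *h*/2); `normalize=True` rescales every root-to-leaf path to 1,
which some downstream heatmap tools require.

## Cutting and the elbow heuristic

Cutting into *k* patterns undoes the *k*−1 highest merges (ties resolved
toward later merges).  Pattern indices run left to right along the leaf
order; the representative label is the first leaf of the pattern and the
displayed representative is the centroid.

The elbow suggestion uses the merge-height variance profile: with total
(population) variance *V*<sub>T</sub> of all merge heights, the explained
fraction at candidate *k* is the variance of the heights of the merges
undone by cutting into *k* groups, divided by *V*<sub>T</sub>.  With
slope<sub>k</sub> = pct<sub>k+1</sub> − pct<sub>k</sub>, the suggestion
is the *k* maximizing slope<sub>k</sub> − slope<sub>k−1</sub> — the point
where the profile bends upward as within-group merge heights start
entering the undone set.  Candidates run 2..k_max−1 with k_max
defaulting to min(leaves − 1, 50); a dendrogram whose merge heights are
all equal yields 1 with a warning.  Two caveats are worth stating: the
"variance at a cutting height" phrasing admits both an undone-merges and
a remaining-merges reading (the undone reading is implemented), and like
every elbow variant the statistic presumes the planted groups are
separated by *comparable* distances.  When between-group distances are
strongly unequal (one separation twice another) the data are genuinely
hierarchical and the heuristic legitimately reports the coarser grouping;
for that reason the planted-blob generator used to validate recovery
places its cluster centers at the vertices of a randomly rotated regular
simplex, the canonical "G well-separated clusters" with all pairwise
separations equal.

## Inference

t-tests are two-sided by default (one-sided options exist): one-sample
with df = n−1, two-sample either pooled (df = n<sub>x</sub>+n<sub>y</sub>−2)
or Welch with Welch–Satterthwaite fractional df.  p-values come from the
t distribution via SciPy (regularized incomplete beta).  Covariance uses
n−1 normalization and, like correlation, pairwise-complete deletion of
missing cells; zero-variance vectors give missing correlation entries
with a warning.  PCA drops observations with any missing value (warned),
centers internally, orders eigenpairs of the covariance matrix by
descending eigenvalue, and fixes signs so each component's
largest-magnitude loading is positive.  No multiple-testing correction is
applied anywhere.

## Synthetic fixtures

`generate_fixture` emulates the shape of a replicate-combined ChIP-seq
mapping study: a reference BED of gene-like regions (round-robin over
five chromosomes, lengths 1–10 kb, non-overlapping), BroadPeak samples
whose peaks overlap those regions, and `.meta` files with Treatment,
Dose, Duration and Antibody target attributes.  Defaults: 171 reference
regions and 33 samples; three treatment groups of 16/13/4 samples; two
planted row clusters of 72 and 99 regions; block enrichment at
−10·log10(p) ≈ 80 (sd 5) over a background ≈ 15; 10% of
background cells left without any overlapping peak.  Peak significances
are emitted in −10·log10 form by default (the called-peak convention),
with a raw-scale toggle.  Samples are written in shuffled order so that
sorting by treatment metadata is a meaningful first exploration step.
Every byte of output is determined by the seed.

What the fixtures do *not* emulate: realistic peak length/shape
distributions, chromosome-scale coverage biases, overlapping or nested
reference annotations, replicate structure, or correlated noise between
samples.  Tests passing on fixtures therefore demonstrate algorithmic
correctness (joins, transformations, caching, clustering, calibration),
not biological discovery performance on real data.

`blob_space` provides the planted-cluster benchmark for the elbow
heuristic: equidistant Gaussian blobs (simplex centers, separation 50,
spread 1 by default), with ground-truth labels returned alongside.

## Sizes used by the automated checks

The acceptance-style tests run at desk scale: 200 random 8×5 matrices for
the clustering oracle sweep, 100 random MAP instances of up to 50 regions
× 5 samples, 100 random 20-node state trees at capacity 3, 50 replicates
per planted cluster count G ∈ {2..6}, 10,000 simulated null t-tests at
n = 20, and the full 171×33 fixture pipeline for dimension and
determinism checks.  These sizes were chosen to exercise the asymptotic
behavior that matters while keeping the whole suite in the seconds range.

## Known limitations

Sort applies one direction across all keys (no per-key direction).
Bi-clustering is native (complete linkage, Euclidean) rather than
delegated to external tooling, and its result takes no further
transitions.  The MAP join holds per-experiment indexes in memory, so
very large collections should be mapped in batches.  No BAM/VCF input;
gzip is the only compression handled transparently.
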