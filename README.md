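# genospace

A headless Python library and CLI for exploring **genometric spaces**:
matrices whose rows are reference genomic regions (e.g. genes), whose
columns are experiment samples (e.g. ChIP-seq peak sets), and whose cells
aggregate a region attribute over the overlaps between the two.  It is
aimed at bioinformaticians who want the interactive-exploration workflow —
sort, extract, discretize, cluster, inspect patterns, go back, try again —
as scriptable, reproducible building blocks.

## The model

**MAP join.** Given a reference sample *R* with regions *r*<sub>1..n</sub>
and experiment samples *S*<sub>1..m</sub>, the MAP operation builds the
matrix *M* with

> *m*<sub>i,j</sub> = *G*({ v(r) : r ∈ *S*<sub>j</sub>, r overlaps *r*<sub>i</sub> })

where *G* is one of COUNT, MIN, MAX, SUM, AVERAGE, MEDIAN applied to the
values of a chosen numeric attribute (peak p-value, score, …) of the
overlapping regions.  Intervals are 0-based half-open internally; overlap
means at least one shared base.  Empty bags yield 0 under COUNT and a
missing cell (NA) otherwise.  Several (attribute, aggregate) pairs can be
computed in one pass, so a count can ride along with an averaged p-value.

**State transitions.** A space is immutable.  Exploration happens through
six transformations, each a pure function with a JSON-serializable spec:
`Extract([C_l,C_r),[R_u,R_d))`, `Rewrite` (disjoint closed value ranges →
constant or log), `Discretize` (pivot values splitting the value line into
contiguous ranges), `Sort` (stable multi-key, by region attributes or
sample metadata), `Cluster` (agglomerative, single/average/complete
linkage over Euclidean, Manhattan, 1-D earth mover's, Chebyshev, Canberra
or Pearson-correlation distance) and `Bi-Cluster` (rows and columns,
complete/Euclidean, a terminal artifact).  A **state-transition tree**
records every state; only the *n* most recently used non-root states stay
in memory, and evicted states are rebuilt bit-for-bit by replaying the
stored specs from the nearest cached ancestor.

**Patterns.** Cutting a clustering dendrogram into *k* groups yields
patterns with member lists, centroid representatives and per-pattern
counts of metadata attribute-value pairs.  The elbow heuristic suggests
*k* from the variance profile of dendrogram merge heights.  One- and
two-sample t-tests, covariance/correlation matrices and PCA cover the
basic inference needs.

## Worked example

Generate a seeded synthetic dataset shaped like a 33-sample ChIP-seq
study over 171 genes (three treatment groups of 16/13/4 samples; the 13
"Ethanol" samples are enriched over a planted block of 99 genes), map it,
and look for samples with similar enrichment profiles:

```sh
genospace fixture -o fx --seed 5
genospace map --reference fx/reference.bed --experiments fx \
    --aggregate AVERAGE --attribute pValue --extra :COUNT -o space.json
genospace patterns -s space.json --axis columns --k auto -o out
```

which prints

```
suggested k: 2
```

and writes `out/patterns.tsv` beginning

```
pattern	count	label	members
P-0	13	S29.broadpeak	S29.broadpeak;S08.broadpeak;S14.broadpeak;...
P-1	20	S15.broadpeak	S15.broadpeak;S31.broadpeak;S09.broadpeak;...
```

The elbow heuristic finds the two planted enrichment profiles, and the
13-member pattern is exactly the Ethanol treatment group; the
accompanying `out/metadata_counts.tsv` tallies each metadata pair per
pattern (e.g. `Treatment  Ethanol  13  0`), which is how a pattern gets
its biological reading.  A whole exploration — sort columns by treatment,
extract the Ethanol block, sort rows by p-value, drop unenriched genes,
discretize significances into weak/middle/strong — is a JSON chain file:

```sh
genospace replay -s space.json -c chain.json -o final.tsv
```

and replaying it is deterministic: the same seed and chain give the same
bytes.  The same machinery is available as a library (`map_samples`,
`apply_spec`, `STT`, `cluster`, `cut`, `elbow_suggest`, …); sessions can
be saved and lazily reloaded with `session save` / `session load`.

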