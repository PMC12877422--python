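# Methods

## Pairwise alignment and percent identity

All identities are computed from exact dynamic-programming alignments
(Biopython `PairwiseAligner`): Needleman–Wunsch for global identity,
Smith–Waterman for the conservation screen's local hits.  Scoring is
BLOSUM62 with affine gaps in the BLAST convention — a gap of length *k*
costs `open + k·extend` with open = 11, extend = 1.  The ambiguity residue
X scores 0 against everything (neutral treatment).  Terminal gaps are
penalized like internal ones; several published tools instead use
heuristic seeded search (USEARCH, BLASTp), so cluster boundaries obtained
here can differ marginally from heuristic runs on borderline pairs.  The
exact aligner was chosen deliberately: it removes seeding and word-length
degrees of freedom and makes results a pure function of the scoring
scheme.

Percent identity is BLAST-like: `100 · matches / aligned_columns`, where
columns run from the first to the last aligned residue pair — internal
gaps count, terminal gaps do not.  An alternative denominator (shorter
sequence length) is available via `AlignmentParams(identity_mode=
"shorter_seq")`.  Query coverage is the aligned query span over the query
length; for local alignments the span is the local hit itself.  With this
definition, two equal-length sequences differing by *k* substitutions have
identity exactly `100·(L−k)/L`, which is what makes the synthetic
generator's divergence targets exact.  Arguments are canonicalized before
aligning so identity and score are exactly symmetric even when co-optimal
alignments exist.

The test suite checks the aligner against an independently written Gotoh /
Smith–Waterman reference and, on short sequences, against exhaustive
enumeration of *all* optimal alignments, since co-optimal alignments can
legitimately differ in matches and columns.

## Greedy centroid clustering

Records are sorted length-descending (ties by id) and assigned to the
first centroid at identity ≥ threshold, else become centroids — the
UCLUST convention.  Input order matters for any greedy scheme, so the sort
is fixed and documented; a `best`-hit assignment mode exists for
sensitivity analysis.  No k-mer prefilter is applied: at the scale this
package targets (thousands of sequences), exact alignment against every
centroid is affordable and removes a heuristic.  The clustering threshold
defaults to 60 % with a sweep over {40, 50, 60, 70, 80} for resolution
diagnostics; cluster counts are non-decreasing in the threshold, and the
partition at a higher threshold refines the one at a lower threshold
(both properties are tested).

## Profiles, distances, species clustering

Presence is binary by design — a species with several paralogs in one
cluster still scores 1.  Jaccard distances use the conventions
d(∅,∅) = 0 and d(∅,X≠∅) = 1, so species lacking a family entirely remain
placeable (scipy's `jaccard` metric implements exactly this).  "Merging"
per-family distances is the element-wise (optionally weighted) arithmetic
mean over a shared canonical species order; the alternative reading —
concatenating the binary profiles and computing a single Jaccard — is
available as `merge_mode="concat"`.

Hierarchical clustering defaults to UPGMA (average linkage).  Ward
linkage is refused because it assumes squared-Euclidean geometry that
Jaccard distances do not provide; complete and single linkage are
accepted.  Cutting into *k* groups is done by undoing the last *k*−1
merges of the linkage matrix (union-find), which is well defined even
with tied merge heights where threshold-based cutting can return fewer
groups.  Cluster labels C1…Ck follow dendrogram leaf order, so labelings
are stable across runs and platforms.  The default *k* is 10, matching
the resolution used in the reference analysis; no automatic model
selection (silhouette, gap statistic) is attempted.

## Phenotype concordance

Phenotype labels are Cleaver / NonCleaver / Mixed / NA; Mixed and NA
species are excluded before any metric.  ARI and NMI (arithmetic-mean
normalization by default; geometric/min/max selectable) are computed
between the partition restricted to labeled species and the binary
labeling, delegating to scikit-learn; both are verified in the tests
against brute-force pair-counting and entropy oracles over all partitions
of small sets.  Degenerate single-cluster comparisons return 1.0 when the
partitions coincide and warn.

The majority-vote check treats Cleaver as the positive class.  Clusters
with no labeled members are marked Unlabeled and their species do not
enter the confusion counts — this choice affects the accuracy denominator
and is therefore explicit.  Tied clusters default to predicting
NonCleaver, the conservative policy that cannot manufacture false
positives; `cleaver` and `exclude` policies are provided because the tie
rule is genuinely a free choice, and the chosen rule is recorded in every
report.

## Conservation screen

Local (not global) alignment mirrors protein BLAST practice, and coverage
is measured on the query, so short truncated subjects fail the ≥ 30 %
coverage filter while diverged full-length homologs fail the ≥ 60 %
identity filter.  Only the top-scoring subject per (query, strain) is
retained, ties broken by smallest subject id, making the screen fully
deterministic.  No E-values or composition statistics are computed — at
these identity levels the filters, not significance, are binding.
Identity SDs use the sample (n−1) denominator and are reported as 0 when
exactly one strain carries the homolog.  Presence fractions are
monotone non-increasing in both filter thresholds (tested).

## Differential-expression classification

The classifier reproduces the volcano-plot rule with inclusive
thresholds: up/down at |log₂FC| ≥ 1 and adjusted p ≤ 0.05, a separate
class for significant proteins below the fold-change threshold.
Benjamini–Hochberg was chosen as the adjustment — the field standard for
proteomics volcano plots — via statsmodels, and is verified against a
hand-computed step-up in the tests.  The package deliberately starts from
the (protein, log₂FC, p) table: peptide inference, normalization and
imputation are upstream concerns out of scope here.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the pipeline
assumes: enzyme families with clear archetype groups (default 5 per
family, 90 % within-group identity, ≤ 40 % between groups — comfortably
straddling the 60 % clustering threshold), species gene content organized
in blocks, and a phenotype caused by carrying all designated pathway
archetypes.  Species are dealt round-robin into `n_blocks` blocks with
disjoint archetype content; block 0 holds the pathway set.  The default
is two blocks, so the labeled subset maps one-to-one onto the binary
phenotype and a clean run must reach ARI = accuracy = 1; with more
noncleaver blocks than one, a perfect ARI against a binary labeling is
mathematically impossible and the benchmark would conflate model error
with design.  Label noise and Mixed/NA censoring are applied to the
emitted labels only — the underlying truth table is kept.

Simplifications, hence what passing tests do *not* show about real data:
substitution-only mutation (no indels — sacrificed for analytically exact
identities), a uniform residue alphabet with no substitution-matrix-aware
mutation preferences, disjoint block content (real species share accessory
genes across phenotype groups), no phylogenetic correlation between
species, and strain proteomes of a handful of proteins plus random decoys
rather than realistic proteome sizes.  Archetypes are rejection-sampled
(≤ 1000 attempts) to respect the between-group ceiling; at the default
protein length of 200 random draws essentially never collide.

Benchmark problem sizes — 40 species × 2 families × 5 archetypes,
200-residue proteins, 50 strains × 13 reference proteins, 1000-protein
quantification tables — were chosen as the smallest sizes at which every
effect the experiments measure is comfortably resolved, keeping the whole
suite fast on a laptop.

## Numerical and degenerate-input choices

* Distance matrices are validated (symmetry, zero diagonal, range) and
  clipped to [0, 1] against floating-point drift after averaging.
* `cut_dendrogram(k=n)` yields singletons and `k=1` one cluster; both are
  exercised.
* Local alignments with no positive-scoring pair return an empty result
  (score 0) rather than failing; `best_hit` treats them as absent.
* Empty FASTA files parse to empty collections; structural FASTA errors
  report the offending line number.
* All randomness flows from explicit seeds (`numpy.random.default_rng`);
  the pipeline itself is deterministic and seed-free, and equal seeds give
  byte-identical generator output.

## Known limitations

Greedy centroid clustering is order-dependent by construction and is not
a drop-in replica of any specific USEARCH version.  The concordance
metrics are only as meaningful as the label set — with few labeled
species, accuracy and recall have wide sampling error, which is precisely
the regime the null-permutation calibration quantifies.  The conservation
screen assumes one homolog per strain is the relevant one (top score);
lineage-specific duplications are collapsed.
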