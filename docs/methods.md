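# Methods

This note records the model, the numerical and design choices, and the
limits of what the synthetic tests demonstrate.

## Reference preparation

Germline V sequences are handled in IMGT unique numbering: 1-based gapped
coordinates with `.` marking alignment gaps, so that positions such as 316
and 318 mean the same thing across alleles. A reference is prepared for
clustering by

1. keeping functional alleles (pseudogenes and ORFs dropped; alleles of
   unknown functionality are kept unless `strict` is set, since absence of
   an annotation is not evidence of non-functionality);
2. keeping alleles covering position 1 through at least 318 — 5'-truncated
   or short records cannot be compared on equal content;
3. truncating all sequences at position 318. Variation beyond 318 is
   unobservable in repertoire reads because the V 3' end is trimmed during
   recombination, so retaining it would create distinctions no aligner can
   make. Allele pairs that differ only beyond the trim point (in human IGHV,
   IGHV3-66\*01/\*04 and IGHV4-28\*01/\*03 at position 319) collapse here by
   construction;
4. collapsing identical ungapped sequences into one record. The retained
   representative is the natural-sort-smallest IUIS name; that choice is a
   pure determinism device, nothing downstream depends on which synonym
   represents the group.

For export to aligners, `extend_to_full_length` restores original 3' ends;
a collapsed group whose members diverge beyond the trim point is exported
as all distinct full-length sequences under the same ASC name with numeric
suffixes and a provenance flag, because the repertoire data cannot decide
between them.

Partial-coverage protocols are modelled as `AmpliconSpec` windows. S1 is
positions 1–318. The bundled S2 (FW2-primed, start 115) and S3 (minimal 3'
coverage, start 280) starts are deliberate approximations: primer
coordinates are kit-specific and unpublished, so both are plain parameters
meant to be overridden per assay.

## Clustering and the ASC naming scheme

Pairwise dissimilarity is edit distance with unit costs divided by the
longer sequence length. The normalization is a choice: it bounds values in
[0,1], keeps symmetry, and makes "95% similarity" exactly `1 - d`.
Distances are computed on ungapped sequences — Levenshtein already models
indels, so IMGT gap characters would double-count them.

Agglomeration is complete linkage, implemented directly as the naive
O(n^3) loop rather than through a library routine, because the contract
here includes exact determinism: among equally distant cluster pairs, the
pair whose smallest leaf indices come first merges first. Reference sets
are a few hundred sequences, so the cubic cost is irrelevant; the test
suite checks the implementation against an independently written
agglomeration oracle on random sets of up to 8 sequences, exhaustively over
100 seeds.

The tree is cut inclusively (leaves join iff merged at height
`<= 1 - s + 1e-9`; the epsilon guards float representation of rational
heights) at 75% for families and 95% for ASCs. Complete linkage guarantees
the cut property that the maximum intra-cluster dissimilarity is at most
`1 - s`, and that the 75% partition coarsens the 95% partition.

Naming: families F1..Fm and clusters G1..Gn are numbered by ascending
natural-sort-smallest member name, clusters globally across families (a
family can contain G15 without containing G1..G14); allele numbers run
01.. within each cluster in the same order. The ordering policy is a
deterministic convention, not a claim about any published numbering — an
existing key table can be supplied to pin published names, and the key
table is the only authoritative link between naming schemes.

The threshold-evaluation grid reports, per similarity value, the fraction
of IUIS genes split across clusters and the fraction of clusters mixing
genes; the trade-off between the two is what motivates placing the ASC cut
near 95% for full-length human IGHV, and re-evaluating it for other loci,
species or amplicon classes.

## Repertoire processing

AIRR Rearrangement TSVs are read with pandas; `v_call`/`j_call` strings are
split on commas and deduplicated. Filters: one representative per clone
(minimum `v_mutation_count`, ties by smallest `sequence_id`; records
without `clone_id` are singleton clones), zero mutations in positions
1–316 (position 317–318 mutations are tolerated as likely 3'-end
sequencing error), `v_germline_start == 1`, and V alignment length >= 312.
Mutation positions are taken from a `v_mutation_positions` column when
present, else recomputed from gapped alignment strings, else from the plain
count (documented as only valid if pre-restricted). All filters are
idempotent and commute.

## Genotyping

Each translatable record contributes weight 1, split 1/k over the k
distinct ASC alleles of its call, so fractional counts sum exactly to the
number of usable records. Records whose calls are entirely untranslatable
are excluded from the denominator and counted in the log — including them
would deflate every frequency by reads that cannot support any allele.

An allele enters the genotype iff `absolute_frequency >= threshold`. The
comparison is inclusive by decision: at typical depths the threshold sits
exactly at the one-read frequency, and a rule that discards the boundary
read would make the default threshold unreachable at depth 10,000.

The gene-based baseline (allele in iff count/gene-count >= 12.5% or 5%) is
implemented as the plain fraction rule. It exists for comparison reports
only and is a simplification of full gene-based genotyping tools (no
Bayesian smoothing, no novel-allele handling); conclusions about the
baseline from this package are conclusions about the fraction rule, not
about any specific tool.

Undocumented alleles inherit the threshold of their nearest reference
allele (normalized Levenshtein); equidistant ties take the smallest
threshold — the conservative direction, since a too-low threshold admits
an allele for review while a too-high one silently hides it — and are
flagged.

## Haplotype evidence and threshold tuning

For a subject heterozygous at the anchor gene (exactly two anchor alleles
among unambiguous `j_call`s; anything else raises "not haplotypable"), V
fractional counts are split by co-rearranged anchor allele. Column sums
equal the number of anchor-unambiguous records.

The dominance test: with population usage ratio `r` between a cluster's
major and minor allele, a read from the pair is minor with probability
`p = 1/(1+r)` under the null; the reported value is the exact binomial
upper tail `P(X >= k_minor)`. The ratio-to-probability mapping treats `r`
as an odds-like usage ratio; a `rate` parameterization (`p = 1/r`) is
selectable because either reading is defensible for a printed "r times
more" statement. For the 4-vs-1, r = 33 example both round to the same
order of magnitude (4e-6).

Threshold suggestions implement three advisory cases. Case 1 (raise): if
every carrier expresses the allele above `case1_ratio` (default 10) times
its threshold, suggest `raise_factor` (default 0.9) times the minimum
carrier frequency — strictly below the lowest observed expression. Both
knobs are configuration, since "significantly higher" has no canonical
quantitative reading; 10x separates the carrier cloud from the threshold
by an order of magnitude, and 0.9 keeps a margin without overshooting the
next subject. Case 2 (lower): below-threshold expression backed by
haplotype placement with no same-gene conflict suggests lowering to the
lowest supported carrier frequency; two same-gene alleles on one
chromosome flag a contradiction and freeze the threshold. Case 3 seeds
undocumented alleles from their nearest reference allele and re-applies
cases 1–2. Suggestions are never auto-applied (curation is manual), and
the procedure is idempotent by construction: each suggested value is
inside the band that cannot re-trigger its own case.

## Synthetic data

The generator plants known structure: per-gene random base sequences
(redrawn until cross-gene similarity is at most the `between` bound, and
verified), alleles mutated at most `floor(L(1-within)/2)` positions so
within-gene similarity stays above the `within` bound, and duplicated
identical alleles under `D`-suffixed gene names emulating locus
duplications. Repertoires draw each read's allele from the planted
frequencies; defaults are depth 10,000 (the 1e-4 default threshold is
calibrated to 10–20K-read repertoires), per-base mutation rate 1e-3
(naive-like, mostly unmutated), and ambiguity rate 0.1.

Multi-assignments are emitted as the true allele plus its nearest
reference neighbor, but only when that tie is physically possible: an
unmutated read matches its own allele perfectly, so it can only tie with
an *identical* duplicate; mutated reads may tie with any nearest neighbor.
This matters: it is why ASC translation collapses simulated ambiguity
(duplicates share an ASC name) and why genotype recovery is well-posed
(mutation-driven ties are removed by the unmutated filter before usage is
computed).

The generator emulates the statistical structure the genotype method
assumes — skewed planted usage (log-uniform over [1e-3, 1e-1] by
default), fractional ambiguity, chromosome-phased anchor labels. It does
not emulate SHM hotspots, junction diversity, primer bias, clonal
expansion (each simulated read is its own clone), or sequencing-error
models beyond uniform substitution. Passing tests therefore demonstrate
the correctness of the inference machinery under its own model, not
performance on real repertoires; the archive-audit tests are the bridge to
real reference data and require the published archive to be supplied
locally.

All stochastic draws flow from one numpy Generator keyed by the seed, in a
fixed documented order, so all outputs are byte-stable.

## Problem sizes

The test suite and the acceptance script use a reference of 8 genes x 3
alleles (plus duplicates), repertoires of 10,000 reads, 20 replicates for
recovery, 10 subjects for the discordance comparison, and 100 random sets
of up to 8 sequences for oracle equivalence. These sizes make every
statistical check comfortably stable while keeping a full run in seconds.

## Known limitations

- The exact published ASC numbering is reproducible only via a supplied
  key table; the built-in ordering policy is deterministic but its own.
- S2/S3 amplicon windows are approximations until overridden with assay
  primer coordinates.
- The gene-based baseline is the plain fraction rule, not a re-
  implementation of any published genotyping tool.
- Ungapped references are accepted only with an explicit aligned-from-
  position-1 declaration; position-based operations are refused otherwise
  rather than silently miscounting.
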