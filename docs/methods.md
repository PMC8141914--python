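# Methods

## Model and procedure

`circtk` identifies a circRNA solely by its circular junction: the tuple
(chromosome, strand, start, end) with start < end in 1-based fully-closed
coordinates. Nothing is inferred about internal structure — distinct
circles can share a junction and are indistinguishable here.

The detection contract starts at the chimeric junction table, not at reads:
a two-segment split alignment is accepted as a circular chimeric read (CCR)
when

1. both segments are on one chromosome and one strand,
2. the segments are in inverted order — on `+`, the read-prefix segment's
   reference start is strictly greater than the read-suffix segment's
   (mirrored on `-`) — and
3. both segments consume ≥ `min_segment` reference bases (default 15 bp,
   computed from the CIGAR: M, D, N, =, X consume; I, S, H do not).

The junction is derived from segment coordinates, never from the file's
donor/acceptor breakpoint columns, whose semantics drift across aligner
versions; those columns are retained verbatim for cross-checks. On `+`,
junction end = prefix start + prefix span − 1 and junction start = suffix
start; mirrored on `-`. Records deriving start ≥ end are dropped as
inconsistent. Every rejection is counted by reason in a selection report.

Clustering is exact-coordinate with no fuzz window: tolerant clustering
would make identity ill-defined for catalog intersections and orthology.
Support filtering (≥ 5 CCRs) and the size rule (genomic size ≥
read_length/2 + 5, i.e. 55 bp at 100 bp reads, 80 bp at 150 bp) follow the
published protocol; size-excluded candidates stay in the catalog, tagged
`size_excluded`, because small junctions are too often artifactual to
classify yet too numerous to discard silently.

## Classification

Classes and their exact predicates:

* **exonic**: an exon of gene *g* starts at the candidate start and an exon
  of *g* (possibly the same) ends at the candidate end, with candidate
  strand equal to the gene strand. Strand equality is required because
  back-splicing uses the gene's own splice sites; antisense calls are only
  meaningful for the sub-exonic class.
* **intronic**: the candidate lies within one transcript-level intron of
  equal strand, the 5′ junction equals the intron donor exactly, and the 3′
  junction sits 0–60 bp (configurable) inside the intron from the acceptor.
  Introns are derived per transcript (adjacent exon pairs), deduplicated on
  coordinates with all (gene, transcript) attributions retained; splice
  sites are transcript properties, so gene-level merged introns would
  invent donors that no transcript uses.
* **sub-exonic**: both junctions strictly inside a single exon ("strictly":
  a junction touching an exon boundary disqualifies that exon). Sense when
  the host gene's strand matches, antisense otherwise; genes whose biotype
  is in the exclusion set (default `{rRNA}`) never host sub-exonic calls.
* **unannotated**: none of the above. Candidates whose start and end match
  exon boundaries of two *different* genes are flagged `multi_gene` inside
  this class — the exon-fusion geometry is treated as exceptional, not as a
  class of its own.

When several classes match, the primary class follows the precedence
exonic > intronic > sub-exonic (sense) > sub-exonic (antisense): exonic is
the only class with exact evidence at both boundaries, and intronic is
anchored exactly at a donor while sub-exonic requires no boundary at all.
Every alternative match is kept in `all_matches`, so the precedence choice
is auditable per candidate.

The unannotated-cluster scan sorts unannotated circles (including
size-excluded ones, which the catalog treats as non-annotated) and sweeps,
merging neighbors whose junction intervals lie within `window` bp; defaults
window = 10 kb, min_count = 10 are chosen to resolve the 20–300 kb problem
regions such scans are meant to expose without merging chromosome arms.

## Quantification

Counts are junction-read counts (CCRs or BSJ reads). Normalization is
counts × 10⁶ / (library size × TMM factor), with library size the number of
uniquely mapped reads. The TMM implementation follows the published
trimmed-mean-of-M-values estimator: reference column by the
75th-percentile rule, M and A computed over features positive in both
columns, double trimming (30% on M, 5% on A, rank-based with average ranks),
precision weighting by the delta-method variance, and factors recentred to
zero log-mean. It reproduces Bioconductor edgeR's `calcNormFactors` to
1e-8 on random matrices (cross-checked in the test suite via Rscript) and a
loop-level independent transcription of the formula to 1e-6.

Batch expression is the **mean** of normalized per-dataset values. The
protocol describes both summing and averaging normalized counts across a
batch; the two are rank-equivalent within a batch (sum = mean × n), and the
mean is invariant to batch size, so rankings, Top-N overlaps and
correlations are unaffected. Parent-gene expression is the sum over the
gene's circRNAs, with the unannotated mass reported separately so that
gene totals + residual = column totals exactly.

Top-N ranking breaks ties by descending value then lexicographic id, for
reproducible overlap percentages. Cross-species correlations are Pearson on
log10 values (Spearman via flag) over pairs exceeding log10 > 1.2 on both
sides; fewer than three surviving pairs is an error rather than a number.
Batch-versus-batch comparisons of per-dataset summaries use the two-sided
Mann–Whitney test, exact for group sizes ≤ 25 (ties handled by scipy's
exact path); the test is deliberately nonparametric because group sizes in
such designs are small (3–12 per group).

## Orthology

A circRNA's junction sequence is 2 × flank nt (default flank 100) in
transcript orientation: the flank bases ending at the circle's 3′ edge
followed by the flank bases starting at its 5′ edge; minus-strand circles
are the reverse complement of the plus construction. Circles smaller than
the flank wrap around the circle — that is the sequence a junction-crossing
read actually traverses — rather than truncating.

Best hits use local pairwise alignment (Biopython `PairwiseAligner`) with
match +2, mismatch −3, gap open −5, extend −2, and a minimum reported score
of 80. These are conventional megablast-like values; the reciprocal-best-hit
criterion, not the raw score, carries the orthology decision. Random
200-mers score ≈ 20 locally, so the floor of 80 suppresses spurious hits
by a wide margin while a 5%-diverged true partner scores far above it.
Ties for the top score invalidate reciprocity for that query (conservative:
no arbitrary orthology). Gene-level concordance counts pairs whose parent
genes appear in a provided one-to-one ortholog table; pairs with an
unannotated parent are excluded from the denominator.

## Synthetic data

The generator emulates the study's inputs end to end at desk scale: toy
genomes (default two chromosomes, ten genes covering multi-exon
protein-coding genes on both strands, a lncRNA, a pseudogene, a long
mono-exonic gene, an rRNA gene and a ribozyme, with intergenic space),
planted circles of every class at controlled CCR support (5–30 per circle,
straddling the retention threshold), read length 100 bp to mirror the
dominant 2×100 bp datasets, and decoy chimeras — non-inverted (linear
splice), trans-chromosome, strand-mismatched, and under-sized-segment
records — that must never be detected, plus low-support circles that must
cluster but fall to the support filter. Chimeric records are synthesized
directly at the junction-table level so tests never require an aligner.
Segment spans are capped at circle size − 1 because a segment covering the
whole circle would start exactly where its partner starts and no longer be
in strictly inverted order.

The ortholog fixture copies a genome with i.i.d. substitutions at a chosen
rate (default 5%, no indels), lifts the annotation one-to-one, and plants
species-specific decoy circles at loci that host no circle in the other
species. Count matrices are negative-binomial (dispersion 0.1) around
log-normal per-circle means with per-dataset depth factors scaling counts
and library sizes together.

What the generator does **not** emulate: sequencing errors and base
qualities, multi-mapping ambiguity, overlapping genes (planted-truth
recovery is only guaranteed for non-overlapping gene layouts), indels
between species, GC or length biases, and fragment-level dependence between
mates. Passing tests therefore demonstrate correctness of the rules and
plumbing under clean evidence, not robustness to alignment noise in real
libraries.

## Numerical and degenerate-input choices

* Coordinates are 1-based fully-closed everywhere internally; the single
  conversion to 0-based half-open happens at BED emission/parsing.
* A single-end fragment can contribute two CCRs to one junction (mates are
  mapped independently); each read counts once by default, with an optional
  collapse-by-read-name-stem switch.
* Catalog intersections treat strand "." in an external list as matching
  either strand (counted and logged as lenient); the BSJ threshold is
  applied after the intersection, on the quantification-source list's
  counts.
* TMM on a column of all zeros is an error naming the column; two identical
  columns give exactly unit factors.
* `top_n` never ranks zero-expression entries; shorter-than-N lists are
  logged, not padded.
* Dominance ratios for single-isoform genes are reported as `inf` rather
  than omitted.
* Empty catalogs, empty annotations and empty BED files round-trip as empty
  objects without error.

## Problem sizes

Fixtures are sized for interactive use: genomes of ~50 kb per chromosome,
31 planted circles plus 28 decoy records, 1,000-query index oracles,
200 × 4 TMM matrices, and 50 ortholog pairs against 100 decoys (≈ 45,000
local alignments of 200-mers). The full test suite and the acceptance
script each run in well under a minute on one CPU.

## Known limitations

* Only the classic 14-column chimeric dialect (with tolerated trailing
  columns) is parsed; multi-segment chimeras are out of scope.
* Exonic matching requires the same gene, not the same transcript, for the
  two boundary exons; with heavily overlapping annotation this is more
  permissive than a transcript-level rule.
* Orthology supports exactly two species; N-way graphs are out of scope.
* No differential-expression modelling or multiple-testing correction is
  provided; rank-sum p-values are reported raw.
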