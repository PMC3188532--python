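# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical details a maintainer would need.

## Coordinates and input conventions

All internal coordinates are 0-based half-open; conversion happens only at
the I/O boundary (GTF is 1-based inclusive, BED 0-based half-open).
Multi-transcript genes are flattened to the per-gene union of exons, both
for exonic length (RPKM denominator) and for splicing classification; the
pipeline reports at gene level throughout.

"Uniquely mapped" is an input property. For SAM, a record is unique when
it is a primary alignment with MAPQ ≥ 20 and no XA tag; secondary,
supplementary and unmapped records are dropped outright. For BED12 reads,
a 13th column carries the flag (default unique). Coverage, TAR calling and
all downstream evidence use unique reads only; strand is retained on
records but coverage is strand-blind, matching a non-stranded library
protocol.

CIGAR handling: M/=/X and D extend the current reference block (a small
deletion does not open a junction); N closes it; I/S/H/P consume no
reference. Block gaps shorter than 20 bp are not treated as splice
junctions — 20 bp is the conventional floor separating introns from
alignment indels.

## TARs, transcript units, novel units

A TAR is a maximal run of bases with depth ≥ `min_depth` (default 2).
Units are connected components of TARs under fragment evidence: two TARs
are linked when blocks of the same read pair — either mate, including the
blocks of one spliced mate — overlap both. (Linking via a single spliced
mate is a deliberate superset of pair-only linking; a spliced read is
stronger evidence of co-transcription than a mate pair.)

Novelty filters, applied at unit level after linking: the unit span must
lie wholly inside one intergenic interval (genome minus gene spans padded
by `margin` = 200 bp), its longest contiguous covered run (= longest
member TAR) must be ≥ `min_len` = 150 bp, and its average coverage —
averaged over *covered* bases, so mate-pair gap length does not dilute it
— must be ≥ `min_avg_cov` = 2. Clustering merges unit spans separated by
≤ `cluster_gap` = 3000 bp, single linkage, inclusive at the boundary
(the gap is read as a tolerance, so exactly 3 kb merges).

## Splicing classification

Junctions are keyed by (chrom, donor_end, acceptor_start) in genomic
orientation; overhangs are the maxima over supporting reads of the
flanking block lengths. Validation requires `min_junc_reads` = 2 and
`min_overhang` = 5 on both sides. Junctions are assigned to genes by span
containment; junctions inside no gene are reported separately (splicing in
novel regions is outside the classification's scope).

- **ES**: a validated junction joining the end of annotated exon *i* to
  the start of exon *k* with *k − i* ≥ 2; one event per skipped exon.
- **A5SS / A3SS**: two validated junctions sharing one genomic side and
  differing at the other; which type depends on gene strand (the donor is
  the 5' side of the transcribed intron). Pairs in which *both* junctions
  join annotated exon boundaries are excluded: such pairs are
  annotation-consistent splicing (e.g. a skip junction next to its
  canonical neighbour) and would otherwise be double-counted as
  alternative site usage. An alternative-site call therefore always
  involves at least one non-annotated splice site.
- **IR**: an annotated intron whose every base has depth ≥ `min_depth`,
  whose flanking exons are expressed (mean depth ≥ `min_depth`), and which
  no validated junction spans (containment of the intron by the junction
  gap). The coverage-based rule is the minimal definition consistent with
  TAR logic; whether retention could instead be defined by a spliced/
  unspliced read ratio is left open deliberately.

Pooling across samples deduplicates on (gene, type, coordinates) and
reports per-gene distinct-event counts plus the events-per-gene
distribution.

## Boundaries

A TAR is attached to a gene when it overlaps the gene span (coverage
continuity past an annotated end keeps the terminal TAR intact, so
contiguous extension is automatic), or when mate pairs link it into the
same component as an overlapping TAR. A TAR claimable by two genes goes to
the gene with the nearer end; exact ties leave it unassigned (logged). The
extended span is the union of the annotated span with attached TARs;
extensions are measured to the farthest contiguous covered base — no
TSS/TES model is attempted, read support is the only evidence. 5' and 3'
are resolved by strand; a gene extended at both ends yields two records.
All extensions ≥ 1 bp are reported; the summary bins at ≥ 50 bp and counts
the both-ends set as the intersection of the per-end sets.

## Expression and differential expression

RPKM = c / (L/10³) / (N/10⁶) with c the unique reads assigned to the
gene's flattened exons (largest-overlap wins; exact ties unassigned), L
the flattened exonic length, N the library's uniquely mapped reads.

The two-library test conditions on the summed count: given x + y, under
the null y ~ Binomial(x + y, n₂/(n₁+n₂)); the two-sided p doubles the
smaller of the inclusive tails, capped at 1. x = y = 0 carries no evidence
(p = 1) and such genes are excluded before testing. The log₂ ratio is
computed on normalized counts (x/n₁)/(y/n₂) with a half-count floor when
one side is zero — the floor affects the ratio only, never the exact p.
Genome-wide calls use Benjamini–Hochberg step-up q-values
(q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, capped at 1) at q ≤ 0.001 with |log₂ ratio| ≥ 1;
miRNA calls use raw p < 0.01 with the same ratio threshold (small miRNA
universes make FDR control over-aggressive there, and the thresholds are
part of the pipeline's canonical configuration).

GO enrichment: upper-tail hypergeometric P(X ≥ k) per term, Bonferroni
over the tested terms (those with ≥ 1 background and ≥ 1 DE gene),
significance at corrected p ≤ 0.05. The background universe is
configurable and defaults to all annotated genes.

## Small RNA

Adapter trimming cuts at the earliest position from which the read's
remainder is an exact prefix of the adapter; inserts outside 18–30 nt are
dropped, U is normalized to T, identical sequences collapse with summed
counts. The annotation cascade assigns the first matching category in the
fixed order rRNA > tRNA > scRNA/snRNA/snoRNA > repeat > exon > intron
(sequence-substring matching against per-category reference pools;
precedence is a determinism choice — structural RNA first — since no
natural ordering exists). Categories up to and including exon are excluded
before miRNA analysis; intronic and unannotated tags are retained.

Known-miRNA matching allows ≤ 2 substitutions with a ≤ 2 nt terminal
shift (isomiR tolerance): the shorter sequence slides up to 2 positions
along the longer, overhangs are free, and the distance is the minimum
Hamming distance over the overlap. A tag goes to the nearest mature
sequence; ties split the count evenly and are flagged. TPM = count · 10⁶ /
clean-read total.

## GWAS integration

Per trait, only the most significant Bonferroni-corrected SNP is used
(ties keep all tied SNPs). Distance is measured from the nearest base of
the gene span to the SNP (0 inside the gene), inclusive at the window
(default 2.5 Mb — chosen for the extensive LD of an F₂ cross, where a
single window substitutes for LD computation). Genes without a placement
are skipped with a warning. Knockout-phenotype annotation is a plain
lookup; a candidate is trait-flagged when the phenotype text mentions the
trait.

## Synthetic data: what it emulates, what it does not

The generator lays out a single-chromosome genome (default 1 Mb) with 60
non-overlapping genes (2–8 exons of 120–300 bp, introns 150–400 bp) and 50
intergenic novel units (first block 400–600 bp so a ≥ 150 bp covered run
survives edge effects), all features separated by 3.2–4.8 kb so the 200 bp
margins are realizable and clusters stay distinct. Per gene it plants at
most one feature: 10 events of each splicing type (alternative sites shift
a splice site by 10–30 bp into the exon; IR genes express only the
intron-retained isoform) and 16 boundary-extension records of 60–500 bp on
12 genes.

Reads are emitted directly as alignments — mapping is upstream of this
pipeline, so simulating base sequences would exercise nothing in scope.
Fragments are Poisson in number with uniform starts within each expressed
isoform (90 bp mates, 200 bp insert, 10× expected depth; genes carrying an
alternative-site or skipping event split depth across two isoforms), and
projection through the isoform's exon chain produces spliced blocks and
intron-spanning mate pairs naturally. Three deterministic guarantee
mechanisms sit on top, because finite-depth Poisson sampling cannot
promise the constructions the planted truth asserts: three junction-
centered reads per planted junction (≥ 5 bp overhangs), a two-phase 90 bp
tiling over each retained intron (±50 bp), and the same tiling over each
planted extension anchored 50 bp into the gene body (without it, terminal
coverage ramps truncate recovery by more than a read length a few percent
of the time). A 1% fraction of multi-mapping decoy reads checks the
uniqueness filters.

Count tables are Poisson with every gene at rate 50; regulated genes have
one library's rate multiplied by 2^1.5 (direction random), so the baseline
library always keeps the stated mean — dividing the down-regulated side
instead would halve those genes' counts and change the operating
characteristics the defaults are meant to represent. Small-RNA tags mix a
50% mature-miRNA fraction (Dirichlet-skewed abundances; 70/20/10% exact/
1-sub/2-sub variants; mature references fixed at the canonical 22 nt so
the planted length mode is structural) with category-derived substrings at
a fixed mixture, lengths peaked at 22 nt.

Not emulated: sequencing errors and quality strings, GC and positional
bias, stranded protocols, multi-chromosome genomes, overlapping genes,
isoform-level quantification, biological replicate variance
(overdispersion — the exact test's Poisson assumption is also the
generator's, which is exactly why null calibration holds and why real-data
FDRs would be anti-conservative under biological noise). Passing recovery
tests therefore demonstrate algorithmic correctness under the model's own
assumptions, not robustness to real-library artifacts.

## Determinism and problem sizes

All randomness flows from a single seed through named numpy Generator
streams (`[seed, k]` seed sequences per component), and every writer emits
deterministic column order, so same-seed runs are byte-identical — the run
manifest checksums (SHA-256) make this checkable. Default problem sizes
(1 Mb genome, ~12 k reads, 2,000-gene count tables, 10,000 small-RNA
reads) keep a full pipeline run under a second and the whole test suite
under ten; they are the scale at which every planted feature is
individually auditable.

## Known limitations

- IR detection needs a coverage track; junction-only inputs skip IR.
- The cascade matches by substring, not alignment; a tag overlapping a
  reference boundary is missed (the generator never produces one).
- `n_linking_pairs` counts fragments whose touched-TAR set lies within the
  unit, not distinct linking edges.
- The GO stage assumes the DE table's gene universe equals the annotation
  universe used for GO assignments.
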