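# Methods

This note documents the models and procedures implemented in
`exsmallrna`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design decisions taken
where the procedure was genuinely open.

## Read preprocessing

Reads are processed in the order: 3′ adapter clipping → 3′ quality
trimming → length filter → sequence collapsing.

* **Adapter clipping.** The 3′ adapter (default: the Illumina TruSeq
  small-RNA adapter, `TGGAATTCTCGGGTGCCAAGG`) is located by exhaustive
  scoring over every start position, allowing a 3′-terminal partial
  overlap of at least 3 nt and `floor(overlap × 0.1)` mismatches; the
  longest overlap wins, ties broken by fewer errors, then leftmost
  position. This is the common 3′-adapter contract (cutadapt-style
  defaults). An exact full-adapter occurrence short-circuits the scan,
  and results are memoized per raw sequence — small-RNA libraries are
  highly redundant, so the scan runs once per distinct sequence.
* **Quality trimming** removes the maximal 3′ run of bases below Q30
  and is applied after adapter clipping.
* **Length filter**: reads shorter than 15 nt are discarded and
  accounted as `too_short`; the too-short fraction is reported against
  the read (count) denominator, not distinct sequences.
* **Collapsing** merges identical sequences into `(sequence, count)`
  records, sorted by count (desc) then sequence. Counts are conserved
  exactly and the result is invariant to input order. Reads containing
  `N` survive trimming but cannot exact-match any reference and fall
  through to `unassigned`/`genome_unaligned`.

## Hierarchical biotype assignment

Matching is staged, and each collapsed read resolves to exactly one
category, so category totals always partition the input counts:

1. **rRNA stage** — exact match (0 mismatches) against the rRNA
   library; matching reads are removed from further analysis.
2. **Genome + miRNA stage** — matching with at most one substitution
   (no indels, Bowtie1 `-v 1`-style), seeded on the first 19 nt.
   Reads absent from the genome become `genome_unaligned`; reads
   hitting the miRNA library become `miRNA`. Because the later
   annotation stage only sees reads that survive this stage, a read
   matching both a miRNA and a tRNA is miRNA.
3. **Annotation stage** — simultaneous exact matching against mature
   tRNA, tRNA 5′/3′ flanks, piRNA, YRNA, other non-coding and
   protein-coding libraries, with at most 40 annotation hits per read.
   Exactly one biotype → that biotype; two or more → `shared`; no hit,
   or more than 40 hits → `unassigned`.

The seed-and-verify matcher is complete for ≤1 substitution: an exact
lookup of the read's first 19-mer finds every alignment whose mismatch
lies outside the seed, and lookups of all 57 one-substitution seed
variants cover mismatches inside it. Reads shorter than the 19-nt seed
are matched exactly by scanning (the short-read rule); sub-seed-length
records are indexed whole. Equivalence with brute-force matching is
asserted in the tests over random read/reference draws.

Design decisions: a read's whole count goes to its single resolved
category (no fractional allocation across multimapped annotations);
tRNA flank hits are reported as their own `tRNA_flank` category, merged
into neither tRNA nor unassigned; reads and references are handled on
the given strand only (small-RNA libraries are stranded); the stage-2
one-substitution rule doubles as the genome-mapping policy for reads
that later fail all annotation stages. For the per-miRNA count matrix a
sequence matching several miRNAs counts once per miRNA; for composition
profiles it counts once in total.

**Composition profiles and QC.** Biotype percentages are computed over
genome-mapped reads (all categories except too-short, rRNA and
genome-unaligned). A zero denominator yields missing percentages, not
zeros. Samples fail QC when the miRNA share of mapped reads is below 5%
(plasma) or 0.5% (urine/saliva); the exclusion rule is a strict `<`, so
a sample exactly at threshold passes.

## tRNA / YRNA fragment analysis

All reads matching a mature parent (including reads whose final category
is `shared` — the tRNA/piRNA overlap would otherwise hide most urine
tRNA fragments) are classified by terminal evidence:

* **F5** if the read is a prefix of any matched parent,
* else **F3** if a suffix (3′ ends are anchored on the CCA-terminated
  mature sequence),
* else **FM** (internal).

Ties prefer terminal evidence and 5′ over 3′: a read that is both a
prefix of one parent and internal to another is F5; a read equal to a
full mature sequence is F5. Reads sharing an anchored end are nested,
and each nested stack is collapsed to its longest member with counts
summed (stacks are built longest-first, so every member is a
prefix/suffix of its stack representative); middle fragments collapse
only when identical. Collapse conserves counts exactly and is
idempotent.

Summaries: end-class percentage splits, family shares (tRNA
isoacceptor family; YRNA parent gene, pseudogenes grouped under their
source gene) of normalized fragment-assigned reads with top-N +
"Other" extraction, and read-length histograms in RPM of genome-mapped
reads. The histograms use pre-collapse read lengths, since collapsed
fragment lengths would hide the underlying read-length modes. One
engine serves both biotypes; a fragment whose parents span several
groups is labelled `ambiguous` rather than split.

## Normalization and cohort statistics

* **RPM** = count × 10⁶ / genome-mapped reads for human biotypes. The
  exogenous profiler uses its own denominator (input reads ≥15 nt);
  both are implemented and labelled distinctly.
* **Median-of-ratios size factors**: `s_j = median_i k_ij / g_i` with
  `g_i` the geometric mean of feature i across samples; features with
  any zero are excluded from the median. Per-sample scaling constants
  are recovered exactly (up to one global factor) on noiseless input.
* **Detection matrices** count features strictly above 10 or 50 raw
  counts in at least one sample and in ≥10%…100% of samples; the grid
  is monotone in both directions. Detection operates on raw counts
  (the thresholds are read counts); CVs operate on normalized counts.
* **Saturation curves** bin samples by million-read increments of
  input depth and report the median detected-feature count per bin
  (midpoint-of-central-pair for even bins). A subsampling mode
  (multivariate hypergeometric draws from one deep sample) is provided
  as an extension for re-estimating the curve without a depth gradient.
* **CV analysis**: miRNAs are kept when exceeding 50 raw counts in
  ≥80% of the analysis samples (the filter is evaluated across the
  whole analysis sample set, not within subjects). CV = sd/mean
  (sample sd, n−1) of median-ratio-normalized counts, so it is
  invariant to rescaling a sample set. Subjects with ≥5 samples each
  contribute an intra-subject CV distribution over miRNAs; the
  inter-subject distribution takes one sample per subject — the first
  by column (collection) order, or a seeded random choice. Each
  subject is compared to the inter-subject distribution with a
  two-sided Wilcoxon rank-sum test: exact permutation enumeration over
  midranks when both groups have ≤12 observations
  (p = P(|T−μ| ≥ |t−μ|) over all label assignments), otherwise the
  normal approximation with tie correction. Raw p-values are reported
  (no multiple-testing correction across subjects).
* **PCA** operates on feature-centered log2(normalized count + 1) —
  the transform is a package choice, stated here because composition
  data spans orders of magnitude and raw-count PCA would be dominated
  by a handful of features. Within each component the
  largest-magnitude loading is made positive so scores are
  reproducible; degenerate components report variance 0. The top-10
  absolute loadings per PC are extracted for reporting.

## Exogenous unique-signature profiling

The signature database is built by k-mer exclusion with k = 24: for
each species, every position whose 24-mer occurs in the host genome
(either strand) or in any other species (either strand) is excluded,
and the maximal surviving runs of ≥24 nt become that species'
signature segments. Profiling is exact substring matching of reads
(≥15 nt, optionally also their reverse complement, since the
strandedness of exogenous content is unknowable) against segments;
covered bases are the union of hit intervals per segment. A species is
significant in a sample only with ≥100 non-overlapping covered bases,
coverage ≥0.5% of its signature length, and ≥10 hits (all boundaries
inclusive); significant species' hit counts are summed up the taxonomy
to genus/family/order/class/phylum. Raising any filter threshold can
only reduce the significant set, and host-derived reads can never hit
a signature by construction. Mismatch-tolerant split-read matching is
out of scope: the significance filters act downstream of unique
matching, which exact matching preserves at this scale.

## Synthetic-data generator

The generator is the package's ground-truth instrument; its defaults
encode the study conditions for each biofluid.

**References** (fixed seed, byte-identical across runs): mature tRNAs
are assembled from random exon bodies (70–73 nt) with `CCA` appended —
the post-transcriptionally added acceptor end — and 50-nt flanks kept
as separate records; 20 isoacceptor families, with isodecoders sharing
their family's 5′ half (mutations confined to the 3′ half), as real
families do. YRNA genes RNY1/3/4/5 (112/101/96/83 nt) plus pseudogene
copies sharing the parent's 5′ half. One piRNA is planted as the exact
30-nt prefix of a GlyGCC tRNA, reproducing the piRNA/tRNA shared-read
phenomenon; 2587-entry-scale realism is not attempted (150 miRNAs, 20
piRNAs, 3 rRNAs by default). The genome embeds every record between
300-nt random uniform intergenic spacers (no repeat structure).
Bacterial "species" are random 3-kb replicons with a toy
species→genus→…→phylum taxonomy.

**Samples**: each read draws a category (too-short / rRNA / exogenous /
genome-derived biotype), then an insert: full sequences for miRNA and
piRNA; end-class- and length-distributed fragments of a
family-/parent-weighted tRNA or YRNA; random substrings for rRNA,
other biotypes, intergenic spacers and bacterial replicons. The 3′
adapter plus downstream primer sequence pads reads to 50 nt (the read
length and quality model are package choices: constant Q37 with an
optional low-quality 3′ tail to exercise trimming). A truth row per
read records category, source record, group, end class and intended
insert length.

**Biofluid defaults** (see `profiles.py` for the full tables):
plasma — YRNA 63% / miRNA 25% of genome-derived reads, tRF ends
38/30/28 (normalized; the published medians total 96), YRF ends
93/0/7, bimodal tRF lengths (18 and 30–33 nt); urine — tRF-dominated
with ends 99/0/1, GlyGCC 86% of tRNA reads (printed family shares used
verbatim, the unprinted remainder of the median table going to the
unlisted-family pool), single 30-nt tRF peak, YRF ends 98/0/2 with the
RNY4 parent weight set to 0.97/0.98 so the joint RNY4×5′ share is 97%;
saliva — large intergenic/unassigned load, 45.5% bacterial reads, tRF
ends 89/1/10. YRF lengths peak at 32 nt in all three fluids. rRNA and
too-short fractions follow the published per-fluid medians.

**Cohorts**: per-miRNA expected abundance = global power-law mean ×
subject effect × sample effect, with effects lognormal(0, inter_sd)
and lognormal(0, intra_sd). The read-level simulator emits full
samples; `simulate_cohort_counts` draws the per-sample miRNA count
matrix directly (multinomial over the same expected proportions) so
cohort statistics can be exercised at realistic depth cheaply.

**What the generator does not emulate**: sequencing errors, RNA
modifications blocking reverse transcription (so the tRF length modes
are imposed, not emergent from modification-induced stops), UMIs,
GC/ligation bias, genome-scale repeat structure, and realistic library
sizes per species. Passing tests therefore demonstrate correctness of
the analysis logic under the stated composition model, not robustness
to these real-data artifacts.

## Problem sizes and numerics

The recovery analyses use 300,000-read urine-like and 200,000-read
plasma-like samples — enough that binomial noise on every recovered
share is well inside a percentage point (the scarcest class, urine
YRNA at ~0.5% of reads, still yields ~1,500 fragment reads) — and
six-subject, six-sample cohorts at 100,000 miRNA reads per sample for
the CV analysis. Oracle-equivalence checks run on ~50-record bundles
(200 reads × 20 seeds), exhaustive Wilcoxon enumeration on groups ≤8,
and the k-mer-exclusion oracle on genomes ≤10 kb. Distribution maps
must sum to 1 within 1e-9; fragment-share and percentage partitions
are asserted to 1e-6; size-factor recovery to 1e-9. All randomness
flows through `numpy.random.default_rng` with explicit seeds, and
every simulated artifact is byte-reproducible for a fixed seed.

## Known limitations

* One-substitution matching only; no indels and no quality-aware
  scores (out of contracted scope for 16–32-nt inserts).
* The annotation-hit cap (40) counts distinct records, which at
  genome scale would differ from counting genomic loci.
* Exogenous profiling is exact-match only and desk-scale; it does not
  reproduce a 4,937-replicon database or estimate abundance beyond RPM.
* The fragment engine anchors 3′ fragments on the CCA-terminated
  mature sequence; CCA-less 3′ fragments are classed FM.
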