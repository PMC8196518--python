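# Methods

`paircomp` compares two closely related genome assemblies — the setting is
two cultivars of a selfing crop such as foxtail millet (*Setaria italica*)
— and reports the layers of divergence a pan-genome study cares about:
one-to-one syntenic blocks, presence/absence variation (PAV), SNPs and
short indels with density-enriched regions, inversions and translocations,
a k-mer genome-size estimate, orthogroup duplication statistics and
CDS/protein consequence calls.  A bundled simulator generates cultivar
pairs with exact truth so that every caller is scored for parameter
recovery rather than merely exercised.

## The simulator

The ancestor (genome A) is i.i.d. random sequence at a configurable GC
content (default 0.46, typical for a millet genome).  The derived cultivar
(genome B) is produced by composing, in this order: inter-chromosomal
translocations, intra-chromosomal translocations, inversions, PAV
deletions and insertions, then short indels and SNPs.  Structural
intervals are drawn mutually disjoint with a 2-kb buffer and 5-kb
chromosome-end margin, which makes the composite of structural edits
order-independent and keeps every truth coordinate exact in both genomes.
Point mutations stay 200 bp clear of fragment boundaries and at least
10 bp from each other, so breakpoints are never perturbed by indel offsets
and no call is intrinsically ambiguous.

Parameters that matter (defaults are the study conditions used by the
test suite and the acceptance script):

| parameter | default | meaning |
|---|---|---|
| `n_chromosomes` x `chrom_length` | 2 x 1 Mb | genome size |
| `snp_rate_background` | 2e-3 /bp | substitutions outside enriched blocks |
| `enriched_fraction`, `enriched_fold` | 0.20, 3.0 | share of genome in high-SNP blocks and their rate multiplier |
| `enriched_block_length`, `enriched_grid` | 200 kb, 50 kb | enriched blocks are runs of lattice cells; the lattice matches the density-analysis window |
| `indel_rate`, `indel_length_p` | 4e-4 /bp, geometric p=0.5, truncated 1–100 bp | short indels; indels share the enrichment multiplier so they co-cluster with SNPs |
| `n_pav_insertions` + `n_pav_deletions` | 15 + 15 | PAV events per genome pair |
| PAV length law | log-uniform 0.6–5 kb with 1% uniform 5–8 kb tail | puts ~99% of mass below 5 kb, most below 2 kb |
| `n_inversions`, ranges | 3, 5–40 kb | inversions in place |
| translocations | 1 intra + 1 inter, 10–30 kb | cut-and-paste, orientation preserved |
| reads | 40x, 100 bp, 0.2% substitution error | single-end, no qualities |

Enriched blocks are placed on a 50-kb lattice, restricted to cells whose
sequence is at least 80% ancestor-derived, so the realized SNP density
inside a planted block stays close to `fold` x background and recovery can
be judged against sharp interval truth.  Real SNP deserts and hotspots are
of course not lattice-aligned; this is a deliberate simplification for
verifiability.

The `TruthSet` carries all edits plus the fragment (liftover) map, and
`TruthSet.apply_to(ancestor)` replays them; a property test asserts byte
identity with the emitted derived genome across many seeds.  A single
`numpy` generator per seed is consumed in a fixed order (ancestor bases;
SV placement; enriched-block choice; per-chromosome mutation sampling;
allele/length draws), so identical seed and config give byte-identical
bundles on any platform.

What the generator does **not** emulate: repeat families and transposable
elements (the dominant content of real PAV), diploidy/heterozygosity,
assembly gaps (N runs), GC heterogeneity along chromosomes, indel-bearing
or quality-scored reads.  Passing recovery tests therefore demonstrate
algorithmic correctness on unique sequence, not robustness to repeats —
on real assemblies the window mapper inherits the usual multi-mapping
caveats.

## The aligner

The classical workflow this mirrors uses nucmer/delta-filter for
block alignment and BWA-MEM for window mapping; `paircomp` substitutes a
self-contained aligner with the same contracts so the pipeline is testable
without external binaries (PAF-like block tables can also be read in from
an external aligner).

*Seeding.*  All maximal exact matches (MEMs) of length >= `min_mem_len`
(default 20) are enumerated by comparing vectorised 2-bit k-mer codes of
both sequences (k = `min_mem_len`); runs of k-mer identities along a
diagonal collapse to exactly the MEM set, because a run boundary implies a
flanking mismatch or an N (N never matches and breaks anchors).  Both
strands are seeded; minus-strand anchors store forward-query coordinates.

*Chaining.*  Co-strand anchors are chained by dynamic programming,
monotone in both coordinates with inter-anchor gaps bounded by
`max_anchor_gap` (default 1 kb; anchor overlaps up to k-1 are allowed and
trimmed later).  The best chain is extracted, its anchors removed, and the
process repeats, so each anchor joins at most one chain.

*Polishing.*  Inter-anchor gaps are closed by unit-cost global alignment
(edlib's Levenshtein path), producing run-length edit lists over
{match, mismatch, insertion, deletion}.  Identity is matches over aligned
columns x 100; block score is aligned columns x identity/100.  A gap whose
reference and query lengths differ by more than twice `band_width`
(default 100) splits the block there — the analogue of a banded aligner
giving up after doubling its band — which stops PAV-scale insertions from
being swallowed as giant indels.  Blocks shorter than `min_block_len`
(200 bp) on the reference are discarded.

*One-to-one filter.*  After dropping blocks below `min_identity`
(default 90%), overlaps of up to `max_trim_overlap` (100 bp; in practice a
few bases of shared boundary k-mers) are trimmed off the lower-scoring
block rather than treated as conflicts.  The remaining conflict graph
(overlap on either genome) is decomposed into connected components and an
exact maximum-weight independent set is found per component by branch and
bound (components above 30 blocks fall back to a greedy order, never seen
in practice).  The output is the maximum-score subset with no overlap on
either genome, rearrangements permitted — strictly stronger than the
sequential reference-then-query passes of the classical tool, and
verified against exhaustive subset search in tests.

*Colinear filter.*  For each reference chromosome the homologous query
chromosome is taken as the one carrying the highest plus-strand score
among one-to-one blocks; the maximum-score chain strictly increasing in
both genomes is then kept (weighted LIS).  Running this on the one-to-one
survivors guarantees the colinear set is a subset of the one-to-one set,
which is what the rearrangement classifier consumes; restricting each
reference chromosome to its homolog prevents an inter-translocated block
from forming its own trivial "colinear" chain and escaping classification.

*Window mapping.*  A window (default 500 bp) is mapped by looking up its
k-mers in a whole-genome index, picking the best chromosome/strand by
total anchor length, chaining with a 500-bp internal gap allowance and
polishing; coverage is aligned (match+mismatch) window bases over the full
window length.  The single best placement is used; secondary hits are
ignored.

## PAV calling

The screened genome is cut into 500-bp windows at 100-bp steps, with a
tail window anchored at the chromosome end so every base is windowed (the
tail-handling rule is a package choice).  A window is *specific* when it
fails to map to the other genome or maps with coverage strictly below 20%.
Flagged windows merge positionally; segments are kept only when strictly
longer than 500 bp.  Both directions are always computed: insertions into
B surface as B-specific segments, deletions from B as A-specific ones.

Segments whose gaps are <= 100 kb chain into candidate clusters
(single-linkage); a chain is a cluster iff PAV sequence covers more than
10% of its span, applied to each maximal chain once, not recursively.
Genes with more than 75% of their CDS bases under PAV segments are PAV
genes (per-transcript, CDS united per transcript).  Term enrichment of a
PAV gene set uses the upper-tail hypergeometric probability P(X >= k)
with Benjamini–Hochberg adjustment across terms; the BH step is a package
choice on top of the raw test.

With 100-bp steps and the 20% rule, a recovered breakpoint is within one
step (±100 bp) of truth; the recovery suite requires >= 90% recall and
precision at that tolerance, and the reference simulation achieves 100%.

## SNPs, indels, density and enrichment

Variants are read column-by-column off the one-to-one blocks only (the
no-ambiguous-placement convention): one SNP per mismatch column (columns
containing N skipped), one indel per gap run.  Indels follow the short
definition, 1–100 bp; longer gap runs are structural/PAV-scale and not
emitted.  Runs of single-base indels at consecutive positions on both
genomes merge into one indel (same-kind, gap-based adjacency — both are
package readings of the merging rule).  Positions are reported in both
genomes; minus-strand blocks are flipped back to forward query
coordinates.

SNP density uses non-overlapping 50-kb tiles from each chromosome start;
the final partial tile keeps its true span.  The enrichment threshold is
`fold` x the mean count over full tiles (fold 1.5), with partial tiles
tested against a pro-rated threshold; a `threshold_override` reproduces a
fixed printed cutoff (e.g. 180 per 50 kb) when a study rounds its
threshold.  Flagged tiles merge across gaps <= 100 kb; a report-level
filter keeps regions spanning > 450 kb when requested.  The per-kb
density summary takes its denominator explicitly, because the appropriate
base (assembly length vs aligned length) is a reporting decision.

## Rearrangement classification

Candidates are one-to-one blocks absent from the colinear set.  A
minus-strand candidate is an inversion.  A plus-strand candidate whose
query chromosome differs from the consensus of its nearest flanking
colinear blocks on the reference is an inter-chromosomal translocation;
one on the consensus chromosome but breaking the flanks' query order is an
intra-chromosomal translocation; one that actually fits its flanks in
order (a filter tie) is not an SV.  Adjacent same-type candidates merge
when gaps on both genomes are <= `max_anchor_gap`.  A chromosome with no
colinear blocks is classified against global order with a warning.  On
the reference simulation all three inversions and both translocations are
recovered with >= 90% reciprocal overlap.

## Genome size and Nx

Canonical k-mers (k = 17, odd so a k-mer never equals its own reverse
complement) are counted over the read set into a depth histogram.  The
error shoulder is cut at the first local minimum of the spectrum (or an
explicit cutoff); the genome size is the k-mer count above the cutoff
divided by the peak depth.  Excluding depths at or below the cutoff from
both the numerator and the peak search is a package choice the bare
formula leaves open.  At 40x with 0.2% read error the estimate is biased
low by roughly the fraction of k-mers hit by an error (~3%), within the
5% band the tests require.  N50/N90 report both the length and the
1-based rank at which the descending cumulative sum reaches the quantile.

## Orthogroup statistics

Orthogroup inference is consumed as a table (gene, species in {A, B},
group or "-"); the package classifies groups by per-species counts:
species-specific (one side only, or unassigned genes), single-copy pair
(1+1), single-copy-duplicated (1+n or n+1), multi-multi.  A duplication
event is a group where one side has strictly more than twice the genes of
the other ("more than twice" read strictly; exactly 2x does not count —
the boundary is tested).  Duplication ratios divide duplicated genes by
their single-copy counterparts, reported to two decimals.

## CDS/protein consequence calls and in-silico PCR

Translation uses the standard code; internal stops raise with the codon
index, ambiguous codons become X with a warning, a trailing stop is
dropped.  Allele pairs of unequal length are globally aligned (unit
costs) before diffing; only substitution columns are reported, labelled
`S626N`-style with 1-based protein positions.  In-silico PCR is exact
matching only — the assay this mirrors succeeded with exact primers, and
mismatch tolerance would add unvalidated parameters; both strands are
searched and products are reported on forward coordinates with a strand
flag and a 20-kb product-length cap.

## Problem sizes and runtime

The reference recovery run is 2 x 1 Mb with ~5,000 SNPs, ~1,000 indels,
30 PAV segments and 5 SVs; it completes in under two minutes on one CPU
and is the size used by the recovery test and the acceptance script.
Oracle-equivalence tests run at 200 bp – 1 kb against quadratic DP and
exhaustive subset search; the k-mer estimator is validated at 200 kb/40x.
These sizes were chosen so the full battery runs comfortably on a laptop
while every statistical band (e.g. the 5% size-recovery tolerance versus
binomial noise) remains meaningful.

## Known limitations

* Unique-sequence assumption throughout: repeats and segmental
  duplications will fragment chains, multi-map windows and inflate PAV
  on real assemblies.
* The aligner's unit-cost (Levenshtein) polishing has no affine gap
  model; long low-complexity indels may be split differently than by an
  affine aligner (alignment-equivalent, position-shifted).
* Reciprocal-exchange translocations produce one event per displaced
  block, so a reciprocal swap counts twice; the convention is documented
  because published event counts generally cannot be audited.
* `enrich_pathways` expects user-supplied gene-to-term mappings; no
  ontology retrieval is performed.
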