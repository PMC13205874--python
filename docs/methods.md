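# Methods

`phasediv` analyses the divergence between the two haplotypes of a single
heterozygous diploid (or, in an allopolyploid, of one phased subgenome
pair): how much of the genome is syntenic, which regions are structurally
rearranged or too diverged to align, which genes exist on only one
haplotype, and whether coding-identical allele pairs nonetheless differ in
expression because of variants in their promoters.  This note records the
models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic data do and do not establish.

## Genome comparison (synteny module)

**Anchors.** The comparison is seeded by k-mers (default k = 31, odd,
11–31) that occur exactly once in *each* assembly, counting both strands
of a k-mer as one object (strand-canonical).  Uniqueness in both genomes
trades sensitivity in repeats for unambiguous chaining — appropriate for
plant genomes where roughly half the sequence is repetitive and any
repeat-borne anchor would be misleading.  Anchors never span an N.  k-mers
are packed two bits per base into 64-bit integers, so matching is exact
(no hashing collisions) and vectorised.

**Chaining.** Anchors are chained greedily in reference order; a chain
breaks on a change of chromosome pair or orientation, on loss of query
monotonicity (increasing for forward chains, decreasing for reverse), or
when the gap on either genome exceeds `max_gap` (default 20 kb, large
enough that a chain continues across any single sub-10-kb indel).  Chains
with fewer than 3 anchors are discarded.

**Backbone and rearrangements.** Per reference chromosome, the query
chromosome carrying the largest total forward-chain span is selected, and
a maximum-weight increasing subsequence (weight = reference span) of its
forward chains forms the syntenic backbone.  Reverse chains to the
backbone chromosome are inversions; chains to other chromosomes, and
forward chains the subsequence excluded (out of order by construction),
are translocations.  Chain-boundary anchors occasionally overlap a
neighbouring chain by a few bases when a junction k-mer matches by
coincidence; the subsequence tolerates overlaps up to k and overlapping
anchors are dropped at the merge, which keeps the backbone strictly
monotone on both genomes.

**Gap classification.** Between consecutive backbone anchors the two gap
sequences (lengths g_r on hap-1, g_q on hap-2) are classified:

- one side empty → INS (extra sequence in hap-2) or DEL (extra in hap-1);
  flanking anchors are flush against clean junctions, so breakpoints are
  exact there;
- both ≥ `hdr_min_len` (500 bp): a bounded-distance global alignment
  (edlib, distance cap `(1 − hdr_max_identity)·max(g_r, g_q)`) decides
  between a highly diverged region (HDR, identity < 0.9) and absorption
  into the syntenic block with interior variants re-called;
- equal lengths: positional comparison; each mismatch column is a SNP.
  Positional rather than alignment-based comparison matters: an optimal
  alignment can swap two adjacent mismatches for an insertion–deletion
  pair of equal cost, producing positionally shifted SNP calls on
  otherwise identical flanks;
- unequal lengths: end-anchored comparison.  The exact common prefix and
  suffix are trimmed; then both end-anchorings of the short remainder
  against the long one are scored, and if either aligns with ≤
  max(2, 30%) mismatches the gap is emitted as one indel plus
  substitution columns.  This is the common real case — a single indel
  whose flanking anchors were pushed outward by a nearby SNP — and a
  global alignment would instead scatter the short side into spurious
  1-bp matches.  Only comparably-sized remainders go to the aligner.

Inversions and translocations are excised from the gaps their spans fall
in (a translocation consumes reference sequence in one chromosome's gap
and query sequence in another's).  Sequence outside every call becomes
NOTAL (haplotype-unique); the final call set covers every base of both
haplotypes exactly once, with SNPs as positional annotations inside
syntenic blocks.  `region_partition_check` audits exactly this invariant
and is run (and asserted) on every simulated dataset.

An HDR with identity near the 0.8 upper end of the simulated range
occasionally contains a surviving unique 31-mer, splitting its call in
two; overlap-based gene categorisation is insensitive to the split.

## The simulator

Hap-2 is only ever produced by applying an explicit edit script to hap-1
— SNPs, insertions, deletions, inversions, cut-and-paste translocations,
same-length HDR resequencing, and haplotype-unique segments — so every
truth record is exact by construction (`apply_edit_script` reproduces
hap-2 byte-for-byte).  Defaults describe a scaled-down heterozygous
genome: 2 chromosomes × 500 kb, SNP rate 0.005/bp, 40 insertions and 40
deletions (log-uniform 50–5000 bp), 2 inversions (5–50 kb), 1
cross-chromosome translocation (5–20 kb), 6 HDRs (2–20 kb, identity
0.6–0.8, substitutions only so truth coordinates stay rectangular), 2
unique segments per haplotype (3–10 kb), and telomeric (TTTAGGG)₃₀ arrays
at both ends of every chromosome.

Genes (120 per chromosome, 12% hemizygous split ≈ 44:52:4 between
insertion-, HDR-, and unique-resident) are placed with ≥ 200 bp spacing;
hemizygous genes sit wholly inside their hosting region with ≥ 250 bp
margins.  Two feasibility constraints are built in: events that must host
a gene draw their lengths from the upper part of the SV length range
(1.8–5 kb), and HDR lengths are inflated (capped at the range maximum) if
the drawn set cannot hold the planned HDR-resident genes.  Unique
segments sit flush against the telomere arrays, so an anchor-based caller
sees them as unaligned sequence rather than giant indels; region truth
covers the non-telomeric sequence exactly once.

Every homozygous pair *not* designated coding-identical receives at least
one guaranteed CDS SNP; without it, a few CDSs would escape the
background SNP rate by chance and the planted identical-pair set would
not be exact.  Identical pairs default to 60, of which 12 carry a
cis-effect: a 4-fold expression shift on one haplotype (direction random
per pair) in all tissues, plus 10 extra planted SNPs in the pair's 3-kb
upstream window — the planted cis-regulatory signal.  The background
promoter burden is whatever the genome-wide SNP/SV rates deposit there
(≈ 15 SNPs per 3-kb window).

Expression counts are negative binomial with Var = μ + 0.1 μ²; baselines
are log-normal(ln 100, 1) per gene pair, tissue effects
log-normal(0, 0.5) shared between haplotypes, hemizygous genes boosted
2-fold (matching the observation that haplotype-specific genes are not
silent annotation artefacts).  Four tissues × 3 replicates.  Genetic-map
markers (30 per chromosome) are strictly monotone in cM along bp with
jittered increments, ≈ 120 cM per chromosome.

Randomness is one seed fanned out through per-stage `SeedSequence`
sub-streams (sequence, events, genes, SNPs, expression, map), so adding a
later stage never perturbs an earlier one.

## Hemizygosity and homolog pairing

A gene is **homozygous** iff some gene of the other haplotype lies within
the syntenic projection of its locus *and* has global CDS identity ≥ 0.9
(edlib Needleman–Wunsch distance over the longer length).  Projection
maps positions linearly through two-sided region calls (reversed inside
inversions); positions in one-sided regions collapse to the flanking
boundary; the candidate window is padded by 1 kb.  Restricting the search
to the projected locus (not genome-wide best hit) prevents translocated
paralogs from rescuing genuinely hemizygous genes.

Hemizygous genes are categorised by largest overlap fraction with the
haplotype-relative insertion view (DEL calls for hap-1 genes, INS calls
for hap-2), HDR intervals, and NOTAL intervals, with a 0.5 floor and tie
priority insertion > HDR > unique; genes reaching no class get
`unassigned` (published category tallies sum to one less than the
hemizygous totals, so an escape class is necessary).  Summary percentages
round the hemizygous share of all genes to the nearest integer and
category shares of the hemizygous total to one decimal (round-half-even).

**Homolog pairs** are reciprocal best hits by CDS identity within the
same projection windows; genes with no candidate or tied best identity
are excluded, so each gene appears in at most one pair.  A pair is
*identical* iff the CDS strings are byte-equal — which subsumes equal
length and renders the identity threshold moot for that flag.

## Expression analysis

TPM: per sample, count/length-in-kb rates scaled to sum to 10⁶ (all-zero
samples give zero columns with a warning rather than NaN).  All tests run
on log2(TPM + 1); the pseudocount makes zero-handling explicit.

**Differential expression between haplotypes** is tested per identical
pair per tissue with a variance-moderated two-sample t-statistic: pooled
per-test variances (4 residual df at 3 + 3 replicates) are shrunk toward
a scaled inverse-chi-square prior whose scale and df are estimated from
the whole pair × tissue family by the method of moments on log variances
(the empirical-Bayes approach standard for few-replicate RNA-seq).  The
moderation is essential, not cosmetic: with 3 replicates an unmoderated
t-statistic at 4 df cannot produce p-values small enough to survive
Benjamini–Hochberg correction over a 240-test family — at the default
study conditions it recovers none of the planted fold-4 effects, while
the moderated test recovers all of them and keeps the null type-I error
at 0.05 within binomial bounds.  BH runs over the full pair × tissue
family (one explicit multiplicity universe); a pair is DE iff any
tissue's q < α (default 0.05).  Note this any-tissue rule inflates
pair-level false flags somewhat when many discoveries raise the BH
threshold — FDR is controlled per test, not per pair.

Hemizygous-vs-homozygous comparisons and the DE-vs-non-DE promoter
burden comparison use two-sided Mann–Whitney U tests on replicate-mean
values, skipped (with notice) when a group has fewer than two members.

## Promoter burden

Promoters are strand-aware 3-kb upstream windows clipped at chromosome
bounds (never overlapping the gene body).  SNP calls are counted by
position; SV-class calls (INS/DEL/INV/TRANS/HDR) count once per call with
≥ 1 bp overlap, where a zero-length breakpoint side (an insertion seen
from the haplotype lacking the sequence) counts when the breakpoint falls
inside the window.  A pair's burden is the **maximum** of its two
haplotypes' promoter burdens — symmetric in the choice of reference side.
No length weighting: a 5-kb HDR and a 60-bp insertion each count once.

## QC

Telomere scan: exact occurrences of the motif and its reverse complement
per 10-kb tiling window (step-1 counting; TTTAGGG cannot overlap itself);
an end is positive when its two terminal windows hold ≥ 10 copies.  Map
concordance: Spearman rho (midranks on ties) of cM vs bp per chromosome,
with |rho| reported for maps stored in reversed orientation; chromosomes
with < 3 markers omit the correlation.  Assembly statistics count
maximal N-runs as gaps.

## Pipeline

`run_all` executes simulate → compare → hemizygosity → homologs → de →
promoters → qc, writing every product through the formats module and a
JSON manifest of content hashes.  A stage is skipped when its recorded
inputs and outputs all hash-match the previous run; any change re-runs
the stage and everything downstream.  An externally produced SyRI-style
region TSV may replace the compare stage; downstream results are then
byte-identical whenever the ingested calls equal the internal ones
(tested).  Everything is single-threaded and deterministic under a fixed
seed; `--threads` is accepted and ignored.

## Coordinates and formats

Internal coordinates are uniformly 0-based half-open; conversion to GFF3/
VCF/TSV (1-based inclusive) and BED (0-based half-open) happens in one
audited module.  A zero-length breakpoint serialises as 1-based
start = end + 1, which is its own arithmetic inverse, so insertion
breakpoints survive the round trip; the region TSV carries two extra base
columns so SNP calls round-trip too, and the VCF writer stores query-side
coordinates in INFO for the same reason.  Indels use the left-anchor-base
VCF convention.

## What the synthetic data do and do not show

Passing tests establish that the algorithms recover *planted* structure
under the stated generative model: uniform random background sequence,
rectangular substitution-only HDRs, clean non-overlapping events with
≥ 600 bp separation, no repeat families, no read-level noise (counts are
drawn, not aligned), and no annotation error.  Real assemblies add
repeat-induced anchor deserts, nested and overlapping variation,
segmental duplications (no DUP class is attempted here), collapsed or
mis-phased regions, and isoform ambiguity — none of which are emulated.
Breakpoint accuracy of ±k bp and the SV size floor of 2k bp are
properties of unique-k-mer anchoring and carry over; the near-perfect
precision/recall figures on simulation are upper bounds, not forecasts
for real data.  Problem sizes (1 Mb per haplotype, 240 genes per
haplotype, 60 identical pairs) were chosen as the smallest at which every
region class, both rearrangement types, and the expression contrasts are
all simultaneously present with non-trivial multiplicity.
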