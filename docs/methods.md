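# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `dupscan`.  It is written for users who need to judge
what the pipeline's numbers mean and what the synthetic-data validation
does and does not establish.

## Scope and data model

The unit of analysis is the **duplication event**: either a single paralog
pair or a *linked set* of neighboring pairs co-duplicated by one mutational
event.  Genes are reduced to one canonical transcript each — the transcript
with the largest summed CDS length, because the homology search operates on
proteins and splice variants would otherwise be reported as paralogs.  All
internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted only at the I/O boundary.  Genes on unplaced
scaffolds are searched but excluded from geography statistics.  Genes whose
canonical CDS carries an internal stop codon or a length not divisible by
three are excluded with a logged warning: these are annotation defects, and
propagating them would corrupt codon alignments downstream.

## Homology search and families

The all-against-all protein search is a word-seeded local alignment:
3-residue exact words shared by two proteins trigger a candidate when two
non-overlapping words co-occur on one diagonal within 100 residues
(the classic two-hit rule); candidates must then reach a raw BLOSUM62 score
of 30 on a triggered diagonal (ungapped Kadane extension) before the full
Smith-Waterman alignment (BLOSUM62, gap open 11 / extend 1) is computed.
Expectation values use the Karlin-Altschul formula E = K m n exp(-lambda S)
with the standard gapped BLOSUM62(11,1) parameters lambda = 0.267,
K = 0.041.  Hits pass at E <= 1e-10 and >= 40 % identity, where identity is
matches over all alignment columns including gaps — the permissive identity
threshold (rather than the 90 % used in many CNV surveys) is deliberate, so
that structurally heterogeneous (partial/chimeric) duplicates are not
excluded at the search stage.  An exhaustive mode that aligns every pair
serves as the completeness oracle in tests, and a precomputed hit table
(TSV) can be substituted for the internal engine.

Families are connected components of the hit graph (single-link: if A hits
B and C, all three are one family regardless of B-C similarity).  Only
families of 2-5 members enter the analysis; large multigene families have
different evolutionary dynamics (and much higher gene-conversion traffic)
and are out of scope.

## Synonymous divergence

K_S is estimated by Nei-Gojobori (1986) counting on a protein-guided codon
alignment:

* synonymous site counts per codon average the fraction of one-step changes
  that preserve the amino acid (changes to stop codons count as
  nonsynonymous, so sites always sum to 3 per codon);
* codons differing at 2-3 positions average their synonymous/nonsynonymous
  difference counts over all minimal mutational pathways, skipping pathways
  through stop codons (if every pathway crosses a stop, all are used);
* proportions are corrected for multiple hits with Jukes-Cantor,
  d = -(3/4) ln(1 - (4/3) p); p >= 3/4 is reported as saturated
  (undefined K_S) and the pair is dropped with a log message.

Counting-based NG86 replaces maximum-likelihood codon models deliberately:
at the K_S <= 0.1 horizon the methods differ at second order, and NG86 is
self-contained and exactly invertible for the simulator (below).  The
protein alignment feeding the codon alignment is **local**
(Smith-Waterman): chimeric paralogs carry recruited coding sequence with no
homolog in the partner, and a global alignment would force those columns
into the NG86 counts and inflate K_S (and corrupt the conversion test's
exchangeability; see below).  Forward simulation under the estimator's
assumptions (uniform codons, no transition bias) shows |bias| < 0.001 at
true K_S in {0.01, 0.05, 0.1} with 500-codon sequences.

Pairs are retained when K_S <= 0.1 inclusive.  Age cohorts are
K_S = 0, 0 < K_S <= 0.025 and 0.025 < K_S <= 0.1, with right-inclusive
boundaries.

## Curation

Three curation steps run between K_S estimation and event construction, in
this order: same-location removal, UPGMA shadow removal, linked-set
merging, then the K_S <= 0.1 filter; a per-run accounting identity verifies
that every initial pair is either an event member or attributed to exactly
one removal class.

**Same-location pairs** (both genes on one chromosome with byte-identical
coding extents) are annotation artifacts — one locus under two names — and
are removed.  The rule is exact interval identity; near-identical overlaps
are kept, since tandem duplicates can legitimately overlap.

**Shadow pairs.** An n-member family arose through n-1 duplication events,
but all-vs-all similarity yields C(n,2) pairs.  A UPGMA tree (average
linkage, scipy) is built from the pairwise K_S matrix; each internal node
contributes one representative pair — the minimum-K_S pair spanning the two
joined clusters, ties broken lexicographically for determinism.  Undefined
(saturated) K_S entries are imputed with the family's maximum defined
distance, which places saturated relationships as oldest; the imputation is
logged.  The remaining pairs are flagged shadows and removed.

**Linked sets.** Pairs (A1,A2) and (B1,B2) merge when A1/B1 are neighbors
(same chromosome, at most one intervening gene by default) and A2/B2 are
neighbors with the same relative order and strand relationship — the
signature of a single duplication copying a multi-gene segment.  A linked
set carries the arithmetic mean of its members' K_S values and is analyzed
as a single event (structure from its lexicographically first member pair,
whose 200-kb window covers the co-duplicated neighbors).  The one-gene
adjacency window is the smallest non-trivial choice and is configurable.

## Gene-conversion screen

Ectopic gene conversion homogenizes a tract between paralogs, resetting
apparent age inside it.  For each pair the screen builds a codon-aware
triplet alignment with an outgroup ortholog (best cross-proteome hit) and
condenses it to polymorphic columns (>= 2 distinct non-gap states).  The
statistic is the longest run of consecutive condensed columns at which the
paralogs match; the null is obtained by permuting condensed column order
(destroying spatial clustering while preserving composition), with the
add-one estimator p = (1 + #{perm >= obs}) / (1 + n_perm), 10,000
permutations by default, and Bonferroni correction across the pairs tested
within a family.  Linked sets are tested per member ORF and flagged
converted if any member is significant.  Events without an outgroup hit are
flagged untested and retained in both dataset variants.  All cohort
statistics are reported twice: for all events and for the
conversion-excluded set.

Two properties of this test deserve emphasis:

* **Exchangeability requires homologous columns.**  The triplet alignment
  is anchored on the paralogs' *local* protein alignment.  With full-length
  alignments, a chimeric paralog's recruited tail forms a column regime
  with a different match density than the homologous region, and the
  permutation null — which assumes exchangeable columns — misreads the
  regime boundary as clustering.  In development this inflated the
  false-positive rate on conversion-free genomes to roughly 12 % of events;
  restricting to the homologous segment restores the nominal rate.
* **The test is mildly conservative.**  The run-length statistic is
  integer-valued, so the achievable significance levels are discrete and
  the largest level not exceeding alpha is typically below it.  Measured
  over large batches of clustering-free negative triplets (5 %-divergent
  pairs, equidistant outgroup), the realized type-I error at alpha = 0.05
  is about 0.03-0.04, independent of the permutation count.  This errs on
  the side of validity: conversion calls are never anti-conservative.

Power depends on the tract length and on the outgroup's divergence — the
columns that carry the signal inside a converted tract are those where the
outgroup differs.  With an equidistant outgroup, sensitivity is ~0.5 for
200-bp tracts in 3 %-divergent pairs and near 1.0 for 300-bp tracts at 5 %;
averaged over tracts of 200-600 bp and divergences of 3-5 % it is ~0.94.
With a very close outgroup (e.g. at the human-chimp scale of K_S = 0.011)
power is low for any tract — a genuine limitation of outgroup-anchored
conversion detection on very young paralogs, not of this implementation.

## Duplication tracts, span and classification

Each pair's genomic neighborhoods (coding extents padded by 200 kb, clipped
at chromosome ends) are aligned with an exact k-mer anchor chain: 31-mers
occurring at most 4 times in the first window are matched (2-bit packed,
sorted-array join), merged along diagonals into blocks (anchor gaps <= 300
bp), and blocks are chained collinearly — both orientations — when
inter-block gaps are <= 5 kb on both loci, or near zero (<= 50 bp) on one
locus.  The one-sided near-zero rule admits spliced junctions: a
retrogene's exon blocks are contiguous on the derived locus while separated
by introns (often > 5 kb) on the donor locus.  Trivial self-matches of
overlapping windows (same chromosome, identical genomic intervals) are
discarded.  If a chain touches the window edge the flank auto-widens to
800 kb once.  The tract is the chain overlapping both focal genes (largest
aligned coverage wins); **span** is the minimum of the two per-locus tract
extents — conservative under interior sequence decay — and the paralog
distance is the gap between the inner breakpoints (zero when tracts touch).

Structural classification is polarity-free (no inference of which copy is
ancestral): *complete* when both CDS extents lie inside their tracts,
*partial* when exactly one CDS is truncated by a breakpoint, *chimeric*
when both are — i.e. the duplicated ORF fragment is completed by coding
sequence from outside the tract.  Containment uses a 200-bp slack because
tract edges erode by up to a few mismatch-free k-mer lengths under flank
divergence.  Unannotated read-through is not inferred: chimeric calls
require the annotated ORF to extend beyond the tract.

Mechanism is *RNA* (retrotransposition) when one paralog's canonical
transcript is intronless, the partner has introns, and those introns are
absent at the intronless locus (< 20 % of intron bp covered by alignment
blocks); a >= 10-nt poly-A run within 50 bp downstream of the intronless
copy is logged as supporting evidence but not required.  Two single-exon
genes default to DNA — no intron-loss signal exists.  Structural classes
are reported for DNA-mediated events; RNA events are the category *retro*.

## Cohort statistics

The G-test is G = 2 sum O ln(O/E) with the Williams correction G' = G/q:
q = 1 + (k+1)/(6n) for goodness of fit, and
q = 1 + (n sum(1/R) - 1)(n sum(1/C) - 1)/(6n(r-1)(c-1)) for r x c
independence; p-values from the chi-square upper tail.  The correction is
on by default — the published statistics this package recomputes (25.1,
0.844, 1.39) are Williams-corrected values of raw Gs 25.72, 0.847 and
1.398 — and can be disabled per call.  Counts may be non-integer: an
intrachromosomal pair contributes one event to its chromosome while an
interchromosomal pair contributes half an event to each, because the
ancestral copy cannot be identified.  Chromosome frequencies are normalized
by protein-coding gene counts and tested against the gene-density
expectation, with an autosomes-only variant.  Centromere analysis bins each
intrachromosomal paralog (half an event) by the distance from the
centromere midpoint to its CDS midpoint in 10-Mb bins and tests against the
genes-per-bin expectation; bins without genes are excluded from the test.
Trends use Kendall's tau-b (span vs K_S, DNA and RNA events separately),
Pearson r with the t-based two-sided p (K_S vs log10 distance,
intrachromosomal pairs; zero distances are excluded from the log and
logged), and the Wilcoxon rank-sum W (as in R's `wilcox.test`: the
Mann-Whitney U of the first sample) with normal approximation and tie
correction for span vs gene length and vs coding extent.

## The simulator

`synthetic_genome` generates what the analysis assumes and nothing more:

* genes are fully coding multi-exon models (4-8 exons, 280-600 codons,
  uniform sense codons, no internal stops) whose **coding extent** follows
  a lognormal law calibrated by its median (25 kb) and mean (65 kb), the
  scale reported for human protein-coding genes; intergenic and intronic
  sequence is uniform-random at GC 0.41 with no repeat structure, keeping
  the anchor aligner's false-positive rate negligible;
* events are planted by copying a tract around a donor gene: *complete*
  copies the whole gene with 2-8-kb margins; *partial* cuts at a codon
  boundary inside the CDS; *chimeric* additionally appends a novel exon
  (plus stop) beyond the alignable tract; *retro* inserts the spliced mRNA
  with a 12-nt poly-A tail.  Inverse orientation reverse-complements the
  fragment.  Insertion points are intergenic and outside all previously
  planted tracts; coordinates of genes, reserved tracts and earlier truth
  records shift with each insertion;
* the derived copy is diverged to a target K_S by substitutions placed
  uniformly on the currently synonymous single-nucleotide changes until the
  pair's NG86 K_S first reaches the target (so the protein is untouched and
  recovery tests are unconfounded by model mismatch); inserted non-coding
  bases mutate at the flank-divergence rate (default 1 %); optional
  conversion tracts overwrite a derived CDS window with the donor sequence
  after divergence;
* the outgroup is the pre-duplication genome with every gene's CDS diverged
  to K_S = 0.011 (the human-chimp scale);
* every event yields a TruthRecord whose fields mirror the pipeline's event
  table, so recovery scoring is a join on the gene pair.

Donors for partial/chimeric events are restricted to '+'-strand genes (a
construction simplification; derived copies still land on both strands via
the orientation flip, so orientation statistics are exercised).  Only the
derived lineage accumulates the pair's divergence; since NG86 measures the
pair distance this is equivalent to splitting it across both lineages.

What the simulator does **not** emulate — repeats and segmental-duplication
landscapes, indel evolution, codon-usage and transition bias, UTRs and
non-coding genes, selection on copies — bounds what passing tests show:
end-to-end recovery (100 % detection and geography, >= 95 % class accuracy,
K_S MAE <= 0.01 on a 5-chromosome genome with 60 planted events) validates
the pipeline's logic and calibration under its own assumptions, not its
robustness to repeat-rich real genomes, where anchor uniqueness and family
sizes behave differently.

## Problem sizes and determinism

The validation studies use a 5-chromosome, ~120-gene, ~15-Mb genome with 60
planted events; the conversion calibration uses 500 negative and 200
positive 1.5-kb triplets at 1,000 permutations; estimator bias uses 200
replicates of 500 codons per K_S level.  These sizes put every
distributional check well inside its Monte-Carlo error while keeping the
full suite fast on one CPU.  All randomness flows from explicit seeds
(numpy PCG64); reruns with the same seeds are byte-identical, and the
pipeline records its seed and configuration in the output directory.

## Known limitations

* The K_S estimator ignores transition/transversion and codon-usage bias;
  on real data NG86 underestimates K_S relative to ML codon models as
  divergence grows (second-order below K_S ~ 0.1).
* The anchor aligner requires exact 31-mer matches; highly diverged flanks
  (>> 5 %) or repeat-dense neighborhoods will fragment or pollute chains.
  Real-genome use at the scale of published surveys would substitute a
  seeded aligner with mismatch-tolerant seeds via the block-table input.
* Conversion detection power collapses for very close outgroups (see
  above); negative results on near-zero-K_S pairs are weak evidence.
* Linked-set merging can join independently planted events whose donors and
  insertions happen to be mutually adjacent; on gene-dense toy chromosomes
  this is visible, and it mirrors the genuine ambiguity of distinguishing
  one segmental event from two adjacent events.
* The orientation of interchromosomal pairs and the polarity
  (ancestral/derived) of any pair are not inferred.
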