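# dupscan

A pipeline for the genome-wide survey of **evolutionarily young gene
duplicates**: find paralog pairs in small gene families, date them by
synonymous divergence, screen for ectopic gene conversion, map each
duplication's tract and breakpoints, and characterize the cohort-level
statistics of how young duplicates are built and where they live.

It is written for molecular-evolution researchers who want the classic
duplicate-gene natural-history questions answered on any annotated genome
(or on simulated genomes with known truth): What fraction of new duplicates
copy the ancestral ORF completely versus partially or chimerically?  Do
paralogs start out on the same chromosome, in direct or inverse orientation,
and does that change with age?  Are duplicates enriched near centromeres?
How large are duplication tracts relative to genes?

## The method

1. **Families.** One canonical transcript per gene (largest summed CDS);
   all-against-all protein search (word-seeded Smith-Waterman, BLOSUM62,
   affine gaps 11/1, Karlin-Altschul E-values) with E <= 1e-10 and >= 40 %
   identity; single-link clustering; families of 2-5 members kept.
2. **Ages.** Protein-guided codon alignment per pair; synonymous divergence
   by Nei-Gojobori (1986) counting with Jukes-Cantor correction,

   K_S = -(3/4) ln(1 - (4/3) S_d/S),

   averaging multiple-hit codons over all minimal mutational pathways.
   Pairs with K_S <= 0.1 are the "young" cohort, split into three age
   classes (K_S = 0, 0 < K_S <= 0.025, 0.025 < K_S <= 0.1).
3. **Curation.** Same-location pairs (identical coordinates, two names) are
   dropped; within 3-5-member families a UPGMA tree on the K_S matrix keeps
   n-1 representative pairs (one per internal node, minimum-K_S cross-pair)
   and discards shadow pairs; neighboring collinear pairs co-duplicated by
   one event merge into linked sets with averaged K_S.
4. **Gene conversion.** Each pair plus an outgroup ortholog is codon-aligned;
   the alignment is condensed to polymorphic columns and the longest run of
   consecutive paralog matches is compared with its permutation null
   (Sawyer-style test, add-one p-value, Bonferroni over pairs per family).
   Statistics are reported for both the full and the conversion-excluded
   event sets.
5. **Structure.** The paralogs' genomic neighborhoods (+/- 200 kb, widened
   to 800 kb if needed) are aligned by exact 31-mer anchor chaining; the
   chained tract gives breakpoints and the minimum duplication span, and
   each event is classified complete / partial / chimeric (DNA-mediated) or
   retro (RNA-mediated: intronless copy, absent introns, poly-A signal),
   plus intra/interchromosomal location, orientation and paralog distance.
6. **Cohort statistics.** Williams-corrected G-tests (goodness-of-fit and
   independence), chromosome duplication frequencies normalized by gene
   density with half-event counting for interchromosomal pairs, 10-Mb
   centromere-distance bins, Kendall's tau for span vs K_S, Pearson r for
   K_S vs log10 distance, and Wilcoxon rank-sum for span vs gene length.

A seeded simulator (`dupscan.synthetic_genome`) generates multi-exon
genomes (coding-extent lognormal, median 25 kb / mean 65 kb), plants
duplication events of controlled class, placement, orientation, target K_S
and conversion tracts, and emits truth tables so the whole pipeline can be
validated end to end without any downloads.

## Worked example

Simulate a two-chromosome genome with four planted events and run the full
survey against the simulated outgroup:

```python
from dupscan import (SimConfig, EventSpec, simulate_study,
                     PipelineConfig, analyze, score_recovery)

cfg = SimConfig(n_chromosomes=2, genes_per_chromosome=6)
specs = [
    EventSpec("complete", "intra", "direct",  target_ks=0.02),
    EventSpec("partial",  "intra", "inverse", target_ks=0.05),
    EventSpec("chimeric", "inter", "direct",  target_ks=0.01),
    EventSpec("retro",    "inter", "direct",  target_ks=0.03),
]
study = simulate_study(cfg, seed=11, specs=specs)
result = analyze(study.genome, study.genes, PipelineConfig(seed=1),
                 outgroup=(study.outgroup_genome, study.outgroup_genes),
                 centromeres=study.centromeres)
for ev in result.events:
    print(f"{ev.event_id}  {ev.gene1}/{ev.gene2}  Ks={ev.ks:.4f}  "
          f"{ev.category:<8}  {ev.mechanism}  {ev.location}  "
          f"orient={ev.orientation}  span={ev.span}  dist={ev.distance}")
sc = score_recovery(result.events, study.truth)
print(f"recovery: detection={sc.detection_rate:.2f} "
      f"geography={sc.geography_accuracy:.2f} "
      f"class={sc.class_accuracy:.2f} ks_mae={sc.ks_mae:.4f}")
```

This prints (seed 11):

```
event0001  gene0007/gene10002  Ks=0.0530  partial   DNA  intrachromosomal  orient=inverse  span=76456  dist=453969
event0002  gene0009/gene10001  Ks=0.0220  complete  DNA  intrachromosomal  orient=direct   span=69498  dist=153087
event0003  gene0011/gene10003  Ks=0.0182  chimeric  DNA  interchromosomal  orient=n/a      span=57376  dist=None
event0004  gene0012/gene10004  Ks=0.0328  retro     RNA  interchromosomal  orient=n/a      span=917    dist=None
recovery: detection=1.00 geography=1.00 class=1.00 ks_mae=0.0000
```

Each row is one duplication event: the gene pair, its synonymous divergence
(close to the planted target), the structural category and mechanism the
classifier inferred, where the copy landed, the transcriptional orientation
of intrachromosomal pairs, the minimum duplication span in bp, and the
distance separating intrachromosomal paralogs.  The recovery line joins the
events against the simulator's truth records: all four events were found
with correct geography and class, and the K_S estimates match the planted
values.

The same workflow is available from the shell:

```bash
dupscan simulate --seed 11 --out-dir sim/         # FASTA + GFF3 + truth
dupscan run --fasta sim/genome.fa --gff3 sim/genome.gff3 \
    --outgroup-fasta sim/outgroup.fa --outgroup-gff3 sim/outgroup.gff3 \
    --centromeres sim/centromeres.tsv --out-dir out/ --seed 1
dupscan stats --events out/events.tsv --out out/restats.json
```

`out/` then contains the event table (`events.tsv`), the per-pair K_S table,
the conversion-test table, the statistics report (`statistics.json`, with
`all` and `no_conversion` dataset variants), per-stage counts, UPGMA trees
(newick) and a verbatim config echo.

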