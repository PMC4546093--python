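"""Anchor-chain genomic alignment, tract delineation and classification."""
import pytest

from dupscan.annotation_io import GeneModel, GenomeSequences, Transcript
from dupscan.duplication_structure import (AlignmentBlock, AlignmentBlockSet,
                                           Tract, align_genomic_neighborhoods,
                                           classify_mechanism,
                                           classify_structure,
                                           delineate_duplication_tract,
                                           pair_geography)


def _gene(gid, chrom, cds_intervals, strand="+"):
    tx = Transcript(id=f"{gid}.t", exons=list(cds_intervals),
                    cds=list(cds_intervals))
    g = GeneModel(id=gid, chrom=chrom, strand=strand, transcripts={tx.id: tx})
    g.canonical_id = tx.id
    return g


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def planted_genome(rng):
    """60-kb chromosome with an exact 10-kb tract copied to a second site."""
    seq = _random_seq(rng, 60_000)
    tract = seq[5_000:15_000]
    seq = seq[:40_000] + tract + seq[40_000:]
    genome = GenomeSequences({"chr1": seq})
    gene_a = _gene("ga", "chr1", [(7_000, 7_600), (8_200, 8_800)])
    gene_b = _gene("gb", "chr1", [(42_000, 42_600), (43_200, 43_800)])
    return genome, gene_a, gene_b


def test_exact_duplication_yields_single_full_identity_block(planted_genome):
    genome, ga, gb = planted_genome
    bs = align_genomic_neighborhoods(ga, gb, genome, flank=20_000)
    plus = [b for b in bs.blocks if b.strand == "+"]
    big = max(plus, key=lambda b: b.a_len)
    assert big.identity == pytest.approx(100.0)
    assert big.a_len >= 9_900
    assert big.a_start >= 4_900 and big.a_end <= 15_100


def test_inverted_copy_produces_reverse_strand_chain(rng):
    from Bio.Seq import Seq

    seq = _random_seq(rng, 50_000)
    tract = str(Seq(seq[5_000:12_000]).reverse_complement())
    seq = seq[:35_000] + tract + seq[35_000:]
    genome = GenomeSequences({"chr1": seq})
    ga = _gene("ga", "chr1", [(6_000, 7_000)])
    gb = _gene("gb", "chr1", [(40_000, 41_000)], strand="-")
    bs = align_genomic_neighborhoods(ga, gb, genome, flank=15_000)
    tract_found = delineate_duplication_tract(bs, ga, gb)
    assert tract_found is not None
    assert tract_found.strand == "-"


def test_unrelated_random_windows_give_empty_block_set(rng):
    genome = GenomeSequences({"chr1": _random_seq(rng, 30_000),
                              "chr2": _random_seq(rng, 30_000)})
    ga = _gene("ga", "chr1", [(10_000, 11_000)])
    gb = _gene("gb", "chr2", [(10_000, 11_000)])
    bs = align_genomic_neighborhoods(ga, gb, genome, flank=10_000)
    assert bs.empty
    assert delineate_duplication_tract(bs, ga, gb) is None


def _blockset(blocks):
    return AlignmentBlockSet(a_chrom="chr1", a_window=(0, 100_000),
                             b_chrom="chr2", b_window=(0, 100_000),
                             blocks=blocks)


def test_blocks_with_small_gaps_chain_into_one_tract():
    """Two blocks separated by 500-bp gaps on both loci merge (gap <= 5 kb),
    giving breakpoint-to-breakpoint extent 20 kb."""
    bs = _blockset([AlignmentBlock(0, 10_000, 0, 10_000, "+", 99.0),
                    AlignmentBlock(10_500, 20_000, 10_500, 20_000, "+", 99.0)])
    ga = _gene("ga", "chr1", [(1_000, 9_000)])
    gb = _gene("gb", "chr2", [(1_000, 9_000)])
    tract = delineate_duplication_tract(bs, ga, gb)
    assert tract is not None
    assert tract.a_interval == (0, 20_000)
    assert tract.span == 20_000


def test_blocks_beyond_max_gap_do_not_chain():
    bs = _blockset([AlignmentBlock(0, 10_000, 0, 10_000, "+", 99.0),
                    AlignmentBlock(16_000, 20_000, 16_000, 20_000, "+", 99.0)])
    ga = _gene("ga", "chr1", [(1_000, 9_000)])
    gb = _gene("gb", "chr2", [(1_000, 9_000)])
    tract = delineate_duplication_tract(bs, ga, gb, max_chain_gap=5_000)
    assert tract.a_interval == (0, 10_000)


def test_span_is_minimum_of_locus_extents():
    tract = Tract(a_chrom="chr1", a_interval=(0, 36_000),
                  b_chrom="chr2", b_interval=(100, 41_100),
                  strand="+", n_blocks=3)
    assert tract.span == 36_000


def test_spliced_junction_chains_through_long_donor_side_gap():
    """Retrogene signature: near-zero gap on the derived locus admits a
    chain across a >5-kb intron on the donor locus."""
    bs = _blockset([AlignmentBlock(0, 1_000, 0, 1_000, "+", 99.0),
                    AlignmentBlock(9_000, 10_000, 1_010, 2_010, "+", 99.0)])
    ga = _gene("ga", "chr1", [(100, 900), (9_100, 9_900)])
    gb = _gene("gb", "chr2", [(100, 1_900)])
    tract = delineate_duplication_tract(bs, ga, gb, max_chain_gap=5_000)
    assert tract is not None
    assert tract.span == 2_010  # derived-locus extent is the minimum


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _tract(a_iv, b_iv):
    return Tract(a_chrom="chr1", a_interval=a_iv, b_chrom="chr2",
                 b_interval=b_iv, strand="+", n_blocks=1)


def test_both_cds_inside_tract_is_complete():
    ga = _gene("ga", "chr1", [(2_000, 8_000)])
    gb = _gene("gb", "chr2", [(1_000, 7_000)])
    assert classify_structure(_tract((0, 10_000), (0, 10_000)), ga, gb) == "complete"


def test_one_truncated_cds_is_partial():
    ga = _gene("ga", "chr1", [(2_000, 15_000)])    # continues past breakpoint
    gb = _gene("gb", "chr2", [(1_000, 7_000)])
    assert classify_structure(_tract((0, 10_000), (0, 9_000)), ga, gb) == "partial"


def test_orf_recruiting_sequence_beyond_tract_is_chimeric():
    ga = _gene("ga", "chr1", [(2_000, 15_000)])
    gb = _gene("gb", "chr2", [(1_000, 12_000)])    # ORF continues outside tract
    assert classify_structure(_tract((0, 10_000), (0, 9_000)), ga, gb) == "chimeric"


def test_undetermined_tract_is_unclassified():
    ga = _gene("ga", "chr1", [(0, 100)])
    gb = _gene("gb", "chr2", [(0, 100)])
    assert classify_structure(None, ga, gb) is None


def test_intronless_copy_with_absent_introns_is_rna(rng):
    genome = GenomeSequences({"chr1": _random_seq(rng, 30_000),
                              "chr2": _random_seq(rng, 10_000)})
    partner = _gene("pa", "chr1", [(1_000, 1_600), (5_000, 5_600),
                                   (9_000, 9_600)])
    copy = _gene("co", "chr2", [(1_000, 2_800)])
    # blocks cover only the exons at the intronless locus
    bs = AlignmentBlockSet(a_chrom="chr1", a_window=(0, 30_000),
                           b_chrom="chr2", b_window=(0, 10_000),
                           blocks=[AlignmentBlock(1_000, 1_600, 1_000, 1_600, "+", 99),
                                   AlignmentBlock(5_000, 5_600, 1_600, 2_200, "+", 99),
                                   AlignmentBlock(9_000, 9_600, 2_200, 2_800, "+", 99)])
    mech, _notes = classify_mechanism(partner, copy, bs, genome)
    assert mech == "RNA"


def test_aligned_introns_mean_dna_mechanism(rng):
    genome = GenomeSequences({"chr1": _random_seq(rng, 30_000),
                              "chr2": _random_seq(rng, 30_000)})
    a = _gene("a", "chr1", [(1_000, 1_600), (5_000, 5_600)])
    b = _gene("b", "chr2", [(1_000, 1_600), (5_000, 5_600)])
    bs = AlignmentBlockSet(a_chrom="chr1", a_window=(0, 30_000),
                           b_chrom="chr2", b_window=(0, 30_000),
                           blocks=[AlignmentBlock(500, 6_000, 500, 6_000, "+", 99)])
    assert classify_mechanism(a, b, bs, genome)[0] == "DNA"


def test_two_single_exon_genes_default_to_dna(rng):
    genome = GenomeSequences({"chr1": _random_seq(rng, 10_000)})
    a = _gene("a", "chr1", [(1_000, 2_000)])
    b = _gene("b", "chr1", [(5_000, 6_000)])
    assert classify_mechanism(a, b, None, genome)[0] == "DNA"


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def test_same_chromosome_same_strand_is_intra_direct():
    ga = _gene("ga", "chr1", [(1_000, 2_000)])
    gb = _gene("gb", "chr1", [(5_000, 6_000)])
    loc, orient, dist = pair_geography(ga, gb, _tract((1_000, 2_000), (5_000, 6_000)))
    assert (loc, orient) == ("intrachromosomal", "direct")
    assert dist == 3_000


def test_different_chromosomes_is_inter_with_no_orientation():
    ga = _gene("ga", "chr1", [(1_000, 2_000)])
    gb = _gene("gb", "chr2", [(5_000, 6_000)])
    loc, orient, dist = pair_geography(ga, gb, None)
    assert (loc, orient, dist) == ("interchromosomal", "n/a", None)


def test_overlapping_tracts_have_distance_zero():
    ga = _gene("ga", "chr1", [(1_000, 2_000)])
    gb = _gene("gb", "chr1", [(1_500, 2_500)], strand="-")
    loc, orient, dist = pair_geography(ga, gb, _tract((1_000, 2_000), (1_500, 2_500)))
    assert (loc, orient, dist) == ("intrachromosomal", "inverse", 0)
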