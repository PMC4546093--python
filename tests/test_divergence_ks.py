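"""Codon alignment, NG86 Ks estimation, youth filter and curation steps."""
import math
import warnings

import pytest

from dupscan.annotation_io import GeneModel, Transcript
from dupscan.divergence_ks import (ConsistencyError, ParalogPair,
                                   codon_align_from_protein, detect_linked_sets,
                                   filter_young_pairs,
                                   ks_between_cds, ng86_from_codons,
                                   remove_same_location_pairs,
                                   select_representative_pairs)

# codons whose one-step neighbors never include a stop (keeps conventions
# about stop-adjacent mutations out of the cross-library comparison)
SAFE_CODONS = ["GCA", "GCC", "GCG", "GCT", "GGC", "GGT", "CCA", "CCC", "CCG",
               "CCT", "GTA", "GTC", "GTG", "GTT", "ACA", "ACC", "ACG", "ACT",
               "TCC", "TCT", "CTC", "CTT", "ATC", "ATT", "CGC", "CGT"]


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

def test_gap_free_protein_alignment_gives_three_l_columns():
    cds = "ATGGCTGGATCC"
    aln = codon_align_from_protein("MAGS", "MAGS", cds, cds)
    assert len(aln.row1) == 4
    assert "".join(aln.row1) == cds
    assert "".join(aln.row2) == cds


def test_protein_gap_becomes_three_nt_gap():
    cds1 = "ATGGCTGCAGGATCC"   # M A A G S
    cds2 = "ATGGGATCC"         # M G S
    aln = codon_align_from_protein("MAAGS", "M--GS", cds1, cds2)
    assert aln.row2[1] == "---" and aln.row2[2] == "---"
    assert "".join(aln.row2).replace("-", "") == cds2


def test_translation_mismatch_raises_consistency_error():
    with pytest.raises(ConsistencyError):
        codon_align_from_protein("MK", "MK", "ATGGCT", "ATGAAA")  # MA != MK


# ---------------------------------------------------------------------------
# NG86 estimator
# ---------------------------------------------------------------------------

def test_identical_pair_has_ks_zero():
    res = ks_between_cds("ATG" + "GCT" * 40 + "TAA", "ATG" + "GCT" * 40 + "TAA")
    assert res.ks == 0.0
    assert res.ka == 0.0


def test_ng86_matches_hand_counted_oracle_on_31_codons():
    """30 GCT codons plus GGA vs GGG: every codon here contributes exactly
    one synonymous site (a fourfold third position), so S = 31, Sd = 1 and
    Ks = -3/4 ln(1 - 4/(3*31))."""
    c1 = ["GCT"] * 30 + ["GGA"]
    c2 = ["GCT"] * 30 + ["GGG"]
    res = ng86_from_codons(c1, c2)
    assert res.s_sites == pytest.approx(31.0)
    assert res.sd == pytest.approx(1.0)
    hand = -0.75 * math.log(1.0 - 4.0 / 93.0)
    assert res.ks == pytest.approx(hand, abs=1e-12)
    assert res.ka == 0.0


def test_fourfold_site_substitutions_recover_jc_value(rng):
    """Substitutions at 5 % of fourfold third positions: Ka = 0 and Ks equals
    the closed-form Jukes-Cantor correction of p = 0.05 within 0.01."""
    n = 300
    codons1 = ["GC" + "ACGT"[i] for i in rng.integers(0, 4, n)]  # Ala box
    codons2 = list(codons1)
    picks = rng.choice(n, size=15, replace=False)  # 15/300 = 0.05
    for i in picks:
        third = codons2[i][2]
        codons2[i] = codons2[i][:2] + "ACGT"[("ACGT".index(third) + 1) % 4]
    res = ng86_from_codons(codons1, codons2)
    jc = -0.75 * math.log(1.0 - 4.0 * 0.05 / 3.0)
    assert res.ka == 0.0
    assert res.ks == pytest.approx(jc, abs=0.01)


def test_ng86_agrees_with_independent_library_reference(rng):
    """Cross-check against Bio.codonalign's NG86 implementation on a
    synonymously evolved pair of stop-safe codons."""
    from dupscan.synthetic_genome import evolve_synonymous_jc

    ref = [SAFE_CODONS[i] for i in rng.integers(0, len(SAFE_CODONS), 250)]
    der = evolve_synonymous_jc(ref, 0.07, rng)
    mine = ng86_from_codons(ref, der)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        dn, ds = cal_dn_ds(CodonSeq("".join(ref)), CodonSeq("".join(der)),
                           method="NG86")
    assert mine.ks == pytest.approx(ds, abs=1e-9)
    assert mine.ka == pytest.approx(dn, abs=1e-9)


def test_ks_symmetric_in_row_order(rng):
    from dupscan.synthetic_genome import _random_cds, evolve_synonymous_jc, _codons

    cds1 = _random_cds(rng, 150)
    body = evolve_synonymous_jc(_codons(cds1)[:-1], 0.05, rng)
    cds2 = "".join(body) + "TAA"
    assert ks_between_cds(cds1, cds2).ks == pytest.approx(
        ks_between_cds(cds2, cds1).ks, abs=1e-12)


def test_saturated_pair_has_undefined_ks():
    res = ng86_from_codons(["GCT"] * 40, ["GCA"] * 40)  # every syn site differs
    assert res.ks is None


# ---------------------------------------------------------------------------
# youth filter and curation
# ---------------------------------------------------------------------------

def test_young_filter_is_right_inclusive_at_0_1():
    pairs = [ParalogPair("a", "b", ks=0.1),
             ParalogPair("c", "d", ks=0.1000001),
             ParalogPair("e", "f", ks=None)]
    kept = filter_young_pairs(pairs)
    assert [(p.gene1, p.gene2) for p in kept] == [("a", "b")]


def _gene(gid, chrom, start, end, strand="+", rank_hint=None):
    tx = Transcript(id=f"{gid}.t", exons=[(start, end)], cds=[(start, end)])
    g = GeneModel(id=gid, chrom=chrom, strand=strand, transcripts={tx.id: tx})
    g.canonical_id = tx.id
    return g


def test_same_location_pairs_removed_only_on_exact_identity():
    genes = {
        "a": _gene("a", "chr1", 100, 400),
        "b": _gene("b", "chr1", 100, 400),       # identical extent -> removed
        "c": _gene("c", "chr1", 100, 401),       # 99 % overlap -> kept
        "d": _gene("d", "chr2", 100, 400),       # different chromosome -> kept
    }
    pairs = [ParalogPair("a", "b", ks=0.0), ParalogPair("a", "c", ks=0.0),
             ParalogPair("a", "d", ks=0.0)]
    kept, removed = remove_same_location_pairs(pairs, genes)
    assert [(p.gene1, p.gene2) for p in removed] == [("a", "b")]
    assert len(kept) == 2


def test_upgma_on_five_member_family_retains_four_pairs(rng):
    members = ["g1", "g2", "g3", "g4", "g5"]
    ks = {}
    for i in range(5):
        for j in range(i + 1, 5):
            ks[frozenset((members[i], members[j]))] = float(rng.uniform(0.01, 0.09))
    retained, shadows, newick = select_representative_pairs(members, ks)
    assert len(retained) == 4          # n - 1 duplication events
    assert len(shadows) == 6           # C(5,2) - 4
    assert newick.endswith(";")


def test_upgma_three_member_tie_breaks_lexicographically():
    ks = {frozenset(("A", "B")): 0.01,
          frozenset(("A", "C")): 0.05,
          frozenset(("B", "C")): 0.05}
    retained, shadows, _ = select_representative_pairs(["A", "B", "C"], ks)
    assert set(retained) == {frozenset(("A", "B")), frozenset(("A", "C"))}
    assert shadows == [frozenset(("B", "C"))]


def test_two_member_family_is_a_no_op():
    retained, shadows, _ = select_representative_pairs(
        ["A", "B"], {frozenset(("A", "B")): 0.02})
    assert retained == [frozenset(("A", "B"))]
    assert shadows == []


@pytest.mark.parametrize("n", [3, 4, 5])
def test_retained_pair_count_is_members_minus_one(n, rng):
    members = [f"m{i}" for i in range(n)]
    ks = {frozenset((a, b)): float(rng.uniform(0.001, 0.1))
          for i, a in enumerate(members) for b in members[i + 1:]}
    retained, shadows, _ = select_representative_pairs(members, ks)
    assert len(retained) == n - 1
    assert len(shadows) == n * (n - 1) // 2 - (n - 1)


# ---------------------------------------------------------------------------
# linked sets
# ---------------------------------------------------------------------------

def _neighborhood(genes_spec):
    """genes_spec: list of (id, chrom, start, strand)."""
    return {gid: _gene(gid, chrom, start, start + 1000, strand)
            for gid, chrom, start, strand in genes_spec}


def test_adjacent_collinear_pairs_merge_with_mean_ks():
    genes = _neighborhood([
        ("a1", "chr1", 0, "+"), ("b1", "chr1", 2000, "+"),
        ("a2", "chr1", 50000, "+"), ("b2", "chr1", 52000, "+"),
    ])
    pairs = [ParalogPair("a1", "a2", ks=0.02), ParalogPair("b1", "b2", ks=0.04)]
    singles, linked = detect_linked_sets(pairs, genes)
    assert singles == []
    assert len(linked) == 1
    assert linked[0].ks == pytest.approx(0.03)
    assert len(linked[0].members) == 2


def test_partners_on_different_chromosomes_do_not_merge():
    genes = _neighborhood([
        ("a1", "chr1", 0, "+"), ("b1", "chr1", 2000, "+"),
        ("a2", "chr2", 50000, "+"), ("b2", "chr3", 52000, "+"),
    ])
    pairs = [ParalogPair("a1", "a2", ks=0.02), ParalogPair("b1", "b2", ks=0.04)]
    singles, linked = detect_linked_sets(pairs, genes)
    assert len(singles) == 2 and linked == []


def test_adjacency_on_one_side_only_does_not_merge():
    genes = _neighborhood([
        ("a1", "chr1", 0, "+"), ("b1", "chr1", 2000, "+"),
        ("a2", "chr2", 50000, "+"), ("b2", "chr2", 950000, "+"),  # far apart
        ("x1", "chr2", 100000, "+"), ("x2", "chr2", 200000, "+"),
        ("x3", "chr2", 300000, "+"), ("x4", "chr2", 400000, "+"),
    ])
    pairs = [ParalogPair("a1", "a2", ks=0.02), ParalogPair("b1", "b2", ks=0.04)]
    singles, linked = detect_linked_sets(pairs, genes)
    assert len(singles) == 2 and linked == []
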