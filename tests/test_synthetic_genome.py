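"""Simulator: determinism, calibrated distributions, planting semantics."""
import numpy as np
import pytest

from dupscan.divergence_ks import ng86_from_codons
from dupscan.synthetic_genome import (EventSpec, SimConfig, SimulationError,
                                      _codons, _random_cds,
                                      apply_gene_conversion_tract,
                                      mutate_to_target_ks, sample_coding_extent,
                                      simulate_genome)


def test_same_seed_reproduces_identical_genome_and_annotation():
    cfg = SimConfig(n_chromosomes=2, genes_per_chromosome=4)
    g1, genes1 = simulate_genome(cfg, 5)
    g2, genes2 = simulate_genome(cfg, 5)
    assert {c: g1[c] for c in g1} == {c: g2[c] for c in g2}
    assert [(g.id, g.chrom, g.strand,
             g.transcripts[f"{g.id}.t1"].cds) for g in genes1] == \
        [(g.id, g.chrom, g.strand, g.transcripts[f"{g.id}.t1"].cds) for g in genes2]


def test_requested_gene_count_is_emitted():
    cfg = SimConfig(n_chromosomes=4, genes_per_chromosome=25)
    _genome, genes = simulate_genome(cfg, 11)
    assert len(genes) == 100


def test_coding_extent_sample_median_near_target():
    """500 draws from the lognormal extent law: median within 20 % of 25 kb."""
    cfg = SimConfig()
    rng = np.random.default_rng(99)
    draws = [sample_coding_extent(cfg, rng) for _ in range(500)]
    assert abs(np.median(draws) - 25_000) <= 0.2 * 25_000


def test_genes_do_not_overlap():
    cfg = SimConfig(n_chromosomes=1, genes_per_chromosome=10)
    _genome, genes = simulate_genome(cfg, 3)
    spans = sorted((g.transcripts[f"{g.id}.t1"].cds[0][0],
                    g.transcripts[f"{g.id}.t1"].cds[-1][1]) for g in genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2


# ---------------------------------------------------------------------------
# targeted synonymous mutation
# ---------------------------------------------------------------------------

def test_target_ks_zero_means_no_substitutions(rng):
    sense = _codons(_random_cds(rng, 100))[:-1]
    mutated, realized = mutate_to_target_ks(sense, list(sense), 0.0, rng)
    assert mutated == sense
    assert realized == 0.0


def test_target_ks_first_passage_lands_close(rng):
    sense = _codons(_random_cds(rng, 500))[:-1]
    mutated, realized = mutate_to_target_ks(sense, list(sense), 0.05, rng)
    assert 0.05 <= realized <= 0.06
    assert ng86_from_codons(sense, mutated).ks == pytest.approx(realized)


def test_same_seed_gives_identical_substitution_set():
    rng1, rng2 = np.random.default_rng(17), np.random.default_rng(17)
    sense = _codons(_random_cds(np.random.default_rng(0), 300))[:-1]
    m1, _ = mutate_to_target_ks(sense, list(sense), 0.04, rng1)
    m2, _ = mutate_to_target_ks(sense, list(sense), 0.04, rng2)
    assert m1 == m2


def test_substitutions_preserve_protein(rng):
    from dupscan.annotation_io import translate_cds

    cds = _random_cds(rng, 200)
    sense = _codons(cds)[:-1]
    mutated, _ = mutate_to_target_ks(sense, list(sense), 0.08, rng)
    assert translate_cds("".join(mutated)) == translate_cds("".join(sense))


# ---------------------------------------------------------------------------
# conversion tracts
# ---------------------------------------------------------------------------

def test_whole_cds_tract_resets_ks_to_zero(rng):
    cds = _random_cds(rng, 200)
    sense = _codons(cds)[:-1]
    mutated, realized = mutate_to_target_ks(sense, list(sense), 0.05, rng)
    assert realized > 0
    donor = "".join(sense)
    derived = "".join(mutated)
    homogenized = apply_gene_conversion_tract(donor, derived, (0, len(donor)))
    assert homogenized == donor


def test_empty_tract_leaves_pair_unchanged(rng):
    cds = _random_cds(rng, 50)
    assert apply_gene_conversion_tract(cds, cds[::-1], (0, 0)) == cds[::-1]


def test_tract_homogenizes_inside_and_only_inside(rng):
    cds = _random_cds(rng, 300)
    sense = _codons(cds)[:-1]
    mutated, _ = mutate_to_target_ks(sense, list(sense), 0.08, rng)
    donor, derived = "".join(sense), "".join(mutated)
    out = apply_gene_conversion_tract(donor, derived, (300, 600))
    assert out[300:600] == donor[300:600]
    assert out[:300] == derived[:300]
    assert out[600:] == derived[600:]


def test_tract_outside_cds_raises(rng):
    cds = _random_cds(rng, 50)
    with pytest.raises(SimulationError):
        apply_gene_conversion_tract(cds, cds, (0, len(cds) + 3))


# ---------------------------------------------------------------------------
# event planting (via the session study)
# ---------------------------------------------------------------------------

def test_planted_truth_attributes_match_specs(small_study):
    by_class = {t.event_class: t for t in small_study.truth}
    assert set(by_class) == {"complete", "partial", "chimeric", "retro"}
    for t in small_study.truth:
        assert t.span > 0
        assert (t.distance is not None) == (t.location == "intrachromosomal")
        assert t.realized_ks >= t.spec.target_ks


def test_retro_copy_is_intronless_with_polya(small_study):
    retro = next(t for t in small_study.truth if t.event_class == "retro")
    gene = small_study.gene_map[retro.derived_gene]
    tx = gene.transcripts[f"{retro.derived_gene}.t1"]
    assert len(tx.cds) == 1  # intronless
    lo, hi = tx.cds[0][0], tx.cds[0][1]
    chrom = small_study.genome[gene.chrom]
    if gene.strand == "+":
        assert "A" * 12 in chrom[hi:hi + 60]
    else:
        assert "T" * 12 in chrom[max(0, lo - 60):lo]


def test_conversion_tract_planted_as_identical_window(small_study):
    conv = next(t for t in small_study.truth if t.converted)
    # conversion on a Ks-0 pair leaves realized Ks at 0 by construction
    assert conv.realized_ks == 0.0


def test_invalid_event_specs_rejected():
    with pytest.raises(SimulationError):
        EventSpec("duplicate-ish")
    with pytest.raises(SimulationError):
        EventSpec("complete", target_ks=0.5)


def test_study_outgroup_diverged_near_target(small_study):
    from dupscan.synthetic_genome import _read_cds

    cfg = small_study.config
    seqs = {c: small_study.outgroup_genome[c] for c in small_study.outgroup_genome}
    base = {c: small_study.genome[c] for c in small_study.genome}
    checked = 0
    for gene in small_study.outgroup_genes[:6]:
        focal = next(g for g in small_study.genes if g.id == gene.id)
        out_cds = _read_cds(seqs, gene)
        # compare against the pre-duplication ancestor = focal gene CDS when
        # the gene was not itself mutated (background genes only)
        focal_cds = _read_cds(base, focal)
        if len(out_cds) != len(focal_cds):
            continue
        res = ng86_from_codons(_codons(out_cds)[:-1], _codons(focal_cds)[:-1])
        assert res.ks == pytest.approx(cfg.outgroup_ks, abs=0.01)
        checked += 1
    assert checked >= 3
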