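"""Williams-corrected G-tests, half-event counting, bins and trend stats."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dupscan.cohort_statistics import (COHORTS, assign_cohort,
                                       centromere_distance_bins,
                                       chromosome_duplication_frequencies,
                                       g_test_gof, g_test_independence,
                                       trend_and_rank_stats)
from dupscan.annotation_io import GeneModel, Transcript
from dupscan.duplication_structure import DuplicationEvent


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ks,label", [(0.0, COHORTS[0]), (0.01, COHORTS[1]),
                                      (0.025, COHORTS[1]), (0.03, COHORTS[2]),
                                      (0.1, COHORTS[2])])
def test_cohort_boundaries_right_inclusive(ks, label):
    assert assign_cohort(ks) == label


def test_cohort_out_of_range_raises():
    with pytest.raises(ValueError):
        assign_cohort(0.11)
    with pytest.raises(ValueError):
        assign_cohort(-0.001)


# ---------------------------------------------------------------------------
# G-tests
# ---------------------------------------------------------------------------

def test_orientation_gof_reproduces_published_values():
    """66 vs 77 direct/inverse -> G = 0.844; 54 vs 67 -> G = 1.39."""
    assert round(g_test_gof([66, 77]).g, 3) == 0.844
    assert round(g_test_gof([54, 67]).g, 2) == 1.39


def test_cohort_location_independence_reproduces_published_value():
    """Intra (39, 65, 39) vs inter (0, 9, 20) across three age cohorts:
    Williams-corrected G = 25.1 with df = 2."""
    res = g_test_independence([[39, 65, 39], [0, 9, 20]])
    assert round(res.g, 1) == 25.1
    assert res.df == 2
    assert res.p == pytest.approx(3.59e-6, rel=0.05)


def test_diagonal_two_by_two_matches_hand_computation():
    """[[10,0],[0,10]]: raw G = 2*20*ln2 = 27.7259, q = 1.075 -> 25.7915."""
    res = g_test_independence([[10, 0], [0, 10]])
    assert res.g_raw == pytest.approx(2 * 20 * math.log(2), abs=1e-9)
    assert res.q == pytest.approx(1.075, abs=1e-9)
    assert res.g == pytest.approx(27.725887 / 1.075, abs=1e-4)


def test_equal_observed_counts_give_zero_g():
    assert g_test_gof([10, 10]).g == 0.0


def test_proportional_rows_give_zero_g():
    assert g_test_independence([[10, 20, 30], [1, 2, 3]]).g == pytest.approx(0.0, abs=1e-9)


def test_raw_g_matches_scipy_log_likelihood_ratio():
    obs = [13, 41, 77]
    res = g_test_gof(obs, [0.2, 0.3, 0.5], williams=False)
    g, p = sps.power_divergence(obs, f_exp=[0.2 * 131, 0.3 * 131, 0.5 * 131],
                                lambda_="log-likelihood")
    assert res.g == pytest.approx(g, abs=1e-9)
    assert res.p == pytest.approx(p, abs=1e-9)


@settings(deadline=None, max_examples=60)
@given(st.lists(st.integers(min_value=0, max_value=200), min_size=2, max_size=6)
       .filter(lambda v: sum(v) > 0))
def test_williams_correction_never_increases_g(obs):
    res = g_test_gof(obs)
    assert res.g <= res.g_raw + 1e-12
    if res.g_raw > 0:
        assert res.g < res.g_raw


def test_gof_zero_total_raises():
    with pytest.raises(ValueError):
        g_test_gof([0, 0])


def test_empty_margin_dropped_with_df_adjustment():
    res = g_test_independence([[5, 0, 7], [3, 0, 9]])
    assert res.df == 1


# ---------------------------------------------------------------------------
# half-event chromosome counting
# ---------------------------------------------------------------------------

def _event(eid, g1, g2, c1, c2, ks=0.01, **kw):
    loc = "intrachromosomal" if c1 == c2 else "interchromosomal"
    return DuplicationEvent(event_id=eid, gene1=g1, gene2=g2, ks=ks,
                            chrom1=c1, chrom2=c2, location=loc, **kw)


def test_intra_pair_counts_one_and_inter_counts_half_each():
    events = [_event("e1", "a", "b", "chr1", "chr1"),
              _event("e2", "c", "d", "chr1", "chr2")]
    counts, freqs, _ = chromosome_duplication_frequencies(
        events, {"chr1": 100, "chr2": 100})
    assert counts == {"chr1": 1.5, "chr2": 0.5}
    assert sum(counts.values()) == len(events)
    assert freqs["chr1"] == pytest.approx(0.015)


def test_chromosome_gof_matches_direct_oracle():
    events = [_event(f"e{i}", f"a{i}", f"b{i}", "chr1", "chr1") for i in range(3)]
    events.append(_event("e9", "x", "y", "chr2", "chr2"))
    _c, _f, gtest = chromosome_duplication_frequencies(
        events, {"chr1": 50, "chr2": 50})
    oracle = g_test_gof([3, 1], [0.5, 0.5])
    assert gtest.g == pytest.approx(oracle.g, abs=1e-12)


def test_autosomes_only_excludes_sex_chromosomes():
    events = [_event("e1", "a", "b", "chrX", "chrX"),
              _event("e2", "c", "d", "chr1", "chr1")]
    counts, _f, _g = chromosome_duplication_frequencies(
        events, {"chr1": 50, "chr2": 50, "chrX": 40}, autosomes_only=True)
    assert "chrX" not in counts
    assert counts["chr1"] == 1.0


# ---------------------------------------------------------------------------
# centromere bins
# ---------------------------------------------------------------------------

def _gene_at(gid, chrom, mid):
    tx = Transcript(id=f"{gid}.t", exons=[(mid - 500, mid + 500)],
                    cds=[(mid - 500, mid + 500)])
    g = GeneModel(id=gid, chrom=chrom, strand="+", transcripts={tx.id: tx})
    g.canonical_id = tx.id
    return g


def test_paralog_twelve_mb_from_centromere_lands_in_bin_one():
    genes = {"a": _gene_at("a", "chr1", 62_000_000),
             "b": _gene_at("b", "chr1", 40_000_000)}
    events = [_event("e1", "a", "b", "chr1", "chr1")]
    cen = {"chr1": (50_000_000, 50_000_000)}
    dup, gcounts, _ = centromere_distance_bins(events, cen, genes)
    # a: 12 Mb -> bin 1; b: 10 Mb -> bin 1: both paralogs a half event each
    assert dup[1] == pytest.approx(1.0)


def test_paralogs_in_different_bins_count_half_each():
    genes = {"a": _gene_at("a", "chr1", 55_000_000),   # bin 0
             "b": _gene_at("b", "chr1", 85_000_000)}   # bin 3
    events = [_event("e1", "a", "b", "chr1", "chr1")]
    cen = {"chr1": (50_000_000, 50_000_000)}
    dup, _g, _t = centromere_distance_bins(events, cen, genes)
    assert dup[0] == pytest.approx(0.5)
    assert dup[3] == pytest.approx(0.5)


def test_centromere_gof_matches_direct_oracle():
    genes = {}
    for i in range(10):
        genes[f"g{i}"] = _gene_at(f"g{i}", "chr1", 51_000_000 + i * 2_000_000)
    events = [_event("e1", "g0", "g1", "chr1", "chr1")]
    cen = {"chr1": (50_000_000, 50_000_000)}
    dup, gcounts, gtest = centromere_distance_bins(events, cen, genes)
    keep = gcounts > 0
    oracle = g_test_gof(dup[keep], gcounts[keep] / gcounts[keep].sum())
    assert gtest.g == pytest.approx(oracle.g, abs=1e-12)


# ---------------------------------------------------------------------------
# trends and rank statistics
# ---------------------------------------------------------------------------

def test_strictly_decreasing_span_in_ks_gives_tau_minus_one():
    events = [_event(f"e{i}", f"a{i}", f"b{i}", "chr1", "chr1",
                     ks=0.01 * (i + 1), mechanism="DNA", span=100_000 - i * 10_000)
              for i in range(6)]
    tr = trend_and_rank_stats(events, {})
    tau, _p = tr.kendall_tau_span_ks_dna
    assert tau == pytest.approx(-1.0)


def test_distance_exponential_in_ks_gives_pearson_one():
    events = [_event(f"e{i}", f"a{i}", f"b{i}", "chr1", "chr1",
                     ks=0.01 * (i + 1), distance=int(1e6 * math.exp(0.01 * (i + 1))))
              for i in range(8)]
    tr = trend_and_rank_stats(events, {})
    r, _p, df = tr.pearson_r_ks_logdist
    assert r == pytest.approx(1.0, abs=1e-6)
    assert df == 6


def test_rank_sum_w_equals_brute_force_enumeration(rng):
    spans = [120.0, 340.0, 45.0, 800.0, 222.0]
    lengths = [100.0, 90.0, 350.0, 60.0, 500.0]
    events = [_event(f"e{i}", f"a{i}", f"b{i}", "chr1", "chr1", span=int(s))
              for i, s in enumerate(spans)]
    genes = {}
    for i, L in enumerate(lengths):
        g = _gene_at(f"g{i}", "chr1", 10_000_000)
        tx = g.canonical
        tx.exons = [(0, int(L))]
        tx.cds = [(0, int(L))]
        genes[f"g{i}"] = g
    tr = trend_and_rank_stats(events, genes)
    w, _p = tr.wilcoxon_span_vs_gene_length
    brute = sum(1.0 for s in spans for L in lengths if s > L) + \
        0.5 * sum(1.0 for s in spans for L in lengths if s == L)
    assert w == brute
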