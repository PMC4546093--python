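"""Age-cohort assignment and the statistical battery for duplicate cohorts.

The central tool is the log-likelihood-ratio goodness-of-fit / independence
G-test with the Williams correction, G' = G / q, where for a goodness-of-fit
test over k classes on n observations q = 1 + (k + 1) / (6 n), and for an
r x c independence table q = 1 + (n * sum(1/R) - 1)(n * sum(1/C) - 1) /
(6 n (r-1)(c-1)).  Counts may be non-integer: inter-chromosomal events
contribute half an event to each chromosome because the ancestral copy
cannot be identified.

Also provided: normalized chromosome duplication frequencies (duplicates per
protein-coding gene), 10-Mb centromere-distance binning, and the trend /
rank statistics (Kendall tau for span vs Ks, Pearson r for Ks vs
log10 distance, Wilcoxon rank-sum for span vs gene length).
"""
from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation_io import GeneModel
from .duplication_structure import DuplicationEvent

logger = logging.getLogger(__name__)

COHORTS = ("K=0", "0<K<=0.025", "0.025<K<=0.1")


def assign_cohort(ks: float) -> str:
    """Cohort label for a Ks value in [0, 0.1]; boundaries right-inclusive."""
    if ks < 0:
        raise ValueError(f"negative Ks {ks}")
    if ks == 0:
        return COHORTS[0]
    if ks <= 0.025:
        return COHORTS[1]
    if ks <= 0.1:
        return COHORTS[2]
    raise ValueError(f"Ks {ks} out of range (> 0.1)")


@dataclass(frozen=True)
class GTestResult:
    g: float          # Williams-corrected when williams=True
    g_raw: float
    q: float
    df: int
    p: float


def g_test_gof(
    observed: Sequence[float],
    expected_proportions: Sequence[float] | None = None,
    williams: bool = True,
) -> GTestResult:
    """Goodness-of-fit G-test; G = 2 sum O ln(O/E) with 0 ln 0 = 0."""
    obs = np.asarray(observed, dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("zero total count")
    if expected_proportions is None:
        props = np.full(len(obs), 1.0 / len(obs))
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if not math.isclose(props.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("expected proportions must sum to 1")
    if np.any(props <= 0):
        raise ValueError("expected proportions must be positive")
    exp = n * props
    mask = obs > 0
    g_raw = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))
    k = len(obs)
    q = 1.0 + (k + 1.0) / (6.0 * n) if williams else 1.0
    g = g_raw / q
    df = k - 1
    return GTestResult(g=g, g_raw=g_raw, q=q, df=df, p=float(stats.chi2.sf(g, df)))


def g_test_independence(
    table: Sequence[Sequence[float]], williams: bool = True
) -> GTestResult:
    """r x c independence G-test with Williams correction.

    Empty rows/columns are dropped with a warning (df adjusted).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    keep_r = tab.sum(axis=1) > 0
    keep_c = tab.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping %d empty rows and %d empty columns",
                       (~keep_r).sum(), (~keep_c).sum())
        tab = tab[keep_r][:, keep_c]
        if min(tab.shape) < 2:
            raise ValueError("table degenerate after dropping empty margins")
    n = tab.sum()
    R = tab.sum(axis=1)
    C = tab.sum(axis=0)
    exp = np.outer(R, C) / n
    mask = tab > 0
    g_raw = 2.0 * float(np.sum(tab[mask] * np.log(tab[mask] / exp[mask])))
    r, c = tab.shape
    if williams:
        q = 1.0 + (n * np.sum(1.0 / R) - 1.0) * (n * np.sum(1.0 / C) - 1.0) / \
            (6.0 * n * (r - 1) * (c - 1))
    else:
        q = 1.0
    g = g_raw / q
    df = (r - 1) * (c - 1)
    return GTestResult(g=g, g_raw=g_raw, q=float(q), df=df, p=float(stats.chi2.sf(g, df)))


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def cohort_table(
    events: Iterable[DuplicationEvent], attribute: str
) -> tuple[dict[str, dict[str, float]], list[str]]:
    """Counts of an event attribute per age-cohort -> (cohort -> value -> n)."""
    table: dict[str, dict[str, float]] = {c: {} for c in COHORTS}
    values: list[str] = []
    for ev in events:
        if ev.ks is None:
            continue
        value = getattr(ev, attribute)
        if value is None:
            continue
        cohort = assign_cohort(ev.ks)
        table[cohort][value] = table[cohort].get(value, 0.0) + 1.0
        if value not in values:
            values.append(value)
    return table, sorted(values)


def cohort_contingency(
    events: Iterable[DuplicationEvent], attribute: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """Value x cohort matrix for a categorical event attribute."""
    table, values = cohort_table(events, attribute)
    mat = np.array([[table[c].get(v, 0.0) for c in COHORTS] for v in values])
    return mat, values, list(COHORTS)


# ---------------------------------------------------------------------------
# chromosome and centromere geography
# ---------------------------------------------------------------------------

def _event_chromosomes(ev: DuplicationEvent) -> tuple[str | None, str | None]:
    return ev.chrom1, ev.chrom2


def chromosome_duplication_frequencies(
    events: Iterable[DuplicationEvent],
    genes_per_chromosome: Mapping[str, int],
    autosomes_only: bool = False,
    sex_chromosomes: Sequence[str] = ("chrX", "chrY", "X", "Y"),
) -> tuple[dict[str, float], dict[str, float], GTestResult]:
    """Per-chromosome duplicate counts (half-event convention), relative
    frequencies (per protein-coding gene), and the G-test against the
    gene-density expectation.

    An intrachromosomal pair adds 1 to its chromosome; an interchromosomal
    pair adds 0.5 to each chromosome.  Unassigned events are excluded.
    """
    chroms = {c: n for c, n in genes_per_chromosome.items() if n > 0}
    dropped = set(genes_per_chromosome) - set(chroms)
    if dropped:
        logger.warning("chromosomes with zero annotated genes excluded: %s", sorted(dropped))
    if autosomes_only:
        chroms = {c: n for c, n in chroms.items() if c not in set(sex_chromosomes)}

    counts = {c: 0.0 for c in chroms}
    for ev in events:
        if ev.location == "unassigned" or ev.location is None:
            continue
        c1, c2 = _event_chromosomes(ev)
        if ev.location == "intrachromosomal":
            if c1 in counts:
                counts[c1] += 1.0
        else:
            for c in (c1, c2):
                if c in counts:
                    counts[c] += 0.5
    order = sorted(chroms)
    total_genes = sum(chroms.values())
    freqs = {c: counts[c] / chroms[c] for c in order}
    gtest = g_test_gof([counts[c] for c in order],
                       [chroms[c] / total_genes for c in order])
    return counts, freqs, gtest


def centromere_distance_bins(
    events: Iterable[DuplicationEvent],
    centromeres: Mapping[str, tuple[int, int]],
    genes: Mapping[str, GeneModel],
    gene_index: Mapping[str, tuple[str, int]] | None = None,
    bin_size: int = 10_000_000,
) -> tuple[np.ndarray, np.ndarray, GTestResult]:
    """Duplicate vs gene counts in 10-Mb centromere-distance bins + G-test.

    Distances run from the centromere midpoint to the paralog's CDS midpoint;
    each paralog of an intrachromosomal pair contributes half an event to its
    bin.  Chromosomes without a centromere entry are excluded (logged).
    Returns (duplicate counts, gene counts, G-test of duplicates against the
    gene-density expectation), trimmed to bins that contain genes.
    """
    def midpoint(gene: GeneModel) -> int:
        lo, hi = gene.coding_extent
        return (lo + hi) // 2

    def bin_of(gene: GeneModel) -> int | None:
        cen = centromeres.get(gene.chrom)
        if cen is None:
            return None
        cen_mid = (cen[0] + cen[1]) // 2
        return abs(midpoint(gene) - cen_mid) // bin_size

    missing = set()
    gene_bins: dict[str, int] = {}
    for gid, gene in genes.items():
        if gene.unassigned_location or gene.canonical_id is None:
            continue
        b = bin_of(gene)
        if b is None:
            missing.add(gene.chrom)
            continue
        gene_bins[gid] = b
    if missing:
        logger.warning("chromosomes without centromere entry excluded: %s", sorted(missing))

    n_bins = max(gene_bins.values(), default=0) + 1
    gene_counts = np.zeros(n_bins)
    for b in gene_bins.values():
        gene_counts[b] += 1

    dup_counts = np.zeros(n_bins)
    for ev in events:
        if ev.location != "intrachromosomal":
            continue
        for gid in (ev.gene1, ev.gene2):
            b = gene_bins.get(gid)
            if b is not None:
                dup_counts[b] += 0.5

    keep = gene_counts > 0
    dropped_duplicates = dup_counts[~keep].sum()
    if dropped_duplicates:
        logger.warning("%.1f duplicate half-events fall in bins without genes "
                       "and are excluded from the G-test", dropped_duplicates)
    gtest = g_test_gof(dup_counts[keep], gene_counts[keep] / gene_counts[keep].sum())
    return dup_counts, gene_counts, gtest


# ---------------------------------------------------------------------------
# trend and rank statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendStats:
    kendall_tau_span_ks_dna: tuple[float, float] | None
    kendall_tau_span_ks_rna: tuple[float, float] | None
    pearson_r_ks_logdist: tuple[float, float, int] | None   # (r, p, df)
    wilcoxon_span_vs_gene_length: tuple[float, float] | None
    wilcoxon_span_vs_coding_extent: tuple[float, float] | None


def _kendall(spans: list[float], ks: list[float]) -> tuple[float, float] | None:
    if len(spans) < 3 or len(set(spans)) < 2 or len(set(ks)) < 2:
        return None
    res = stats.kendalltau(spans, ks)
    return float(res.statistic), float(res.pvalue)


def _ranksum_w(x: list[float], y: list[float]) -> tuple[float, float] | None:
    """Rank-sum statistic as in R's wilcox.test (W = U of the first sample),
    normal approximation with tie correction."""
    if len(x) < 3 or len(y) < 3:
        return None
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def trend_and_rank_stats(
    events: Iterable[DuplicationEvent],
    genes: Mapping[str, GeneModel],
) -> TrendStats:
    events = list(events)
    dna = [(ev.span, ev.ks) for ev in events
           if ev.mechanism == "DNA" and ev.span is not None and ev.ks is not None]
    rna = [(ev.span, ev.ks) for ev in events
           if ev.mechanism == "RNA" and ev.span is not None and ev.ks is not None]

    intra = [(ev.ks, ev.distance) for ev in events
             if ev.location == "intrachromosomal" and ev.ks is not None
             and ev.distance is not None]
    excluded = sum(1 for _k, d in intra if d == 0)
    if excluded:
        logger.info("%d intrachromosomal events with distance 0 excluded from "
                    "the log-distance correlation", excluded)
    intra = [(k, d) for k, d in intra if d > 0]
    pearson = None
    if len(intra) >= 3:
        ks_v = [k for k, _ in intra]
        ld = [math.log10(d) for _, d in intra]
        if len(set(ks_v)) > 1 and len(set(ld)) > 1:
            res = stats.pearsonr(ks_v, ld)
            pearson = (float(res.statistic), float(res.pvalue), len(intra) - 2)

    spans = [float(ev.span) for ev in events if ev.span is not None]
    gene_lengths: list[float] = []
    coding_extents: list[float] = []
    for g in genes.values():
        if g.canonical_id is None or g.excluded:
            continue
        exons = g.canonical.exons or g.canonical.cds
        gene_lengths.append(float(exons[-1][1] - exons[0][0]))
        coding_extents.append(float(g.coding_extent_length))

    return TrendStats(
        kendall_tau_span_ks_dna=_kendall([s for s, _ in dna], [k for _, k in dna]),
        kendall_tau_span_ks_rna=_kendall([s for s, _ in rna], [k for _, k in rna]),
        pearson_r_ks_logdist=pearson,
        wilcoxon_span_vs_gene_length=_ranksum_w(spans, gene_lengths),
        wilcoxon_span_vs_coding_extent=_ranksum_w(spans, coding_extents),
    )
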