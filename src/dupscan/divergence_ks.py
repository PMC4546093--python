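"""Codon alignment, NG86 synonymous divergence, and the pair-curation steps.

Ks is estimated with the Nei-Gojobori (1986) counting method: per-codon
synonymous site fractions are averaged over the two sequences, observed
differences at codons differing in 2-3 positions are averaged over all
minimal mutational pathways (skipping pathways through stop codons), and the
raw proportions are corrected for multiple hits with the Jukes-Cantor
transform d = -3/4 ln(1 - 4/3 p).  At the Ks <= 0.1 horizon studied here,
counting and ML codon methods agree to second order.

Curation mirrors the survey's filtering of raw similarity pairs down to
duplication events: *same-location* pairs (identical coordinates under two
gene names: annotation artifacts) are removed; *shadow* pairs inside 3-5
member families (similarity relations that do not correspond to distinct
duplication events) are removed via a UPGMA tree on the pairwise Ks matrix,
keeping one representative minimum-Ks pair per internal node; *linked sets*
(neighboring gene pairs co-duplicated by one event) are merged into single
events carrying the arithmetic-mean Ks.
"""
from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.cluster.hierarchy import linkage

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .annotation_io import GeneModel, translate_cds

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*"))

MIN_ALIGNED_CODONS = 10


class ConsistencyError(ValueError):
    """Protein does not match the translation of its CDS."""


class SaturationError(ValueError):
    """Synonymous proportion beyond the Jukes-Cantor domain (ps >= 3/4)."""


# ---------------------------------------------------------------------------
# NG86 primitives
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon (changes to stops count as
    nonsynonymous, so site counts always sum to 3)."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if CODON_TO_AA[alt] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal mutational pathways that avoid stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    through_stop: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        sd = nd = 0
        current = c1
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                hit_stop = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        (through_stop if hit_stop else valid).append((sd, nd))
    paths = valid if valid else through_stop
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; raises SaturationError at p >= 3/4."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: divergence saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


@dataclass(frozen=True)
class KsResult:
    ks: float | None            # None on synonymous saturation
    ka: float | None
    n_codons: int
    s_sites: float
    n_sites: float
    sd: float
    nd: float

    @property
    def defined(self) -> bool:
        return self.ks is not None


def ng86_from_codons(codons1: Sequence[str], codons2: Sequence[str]) -> KsResult:
    """NG86 Ks/Ka on paired codon lists (already gap/stop free)."""
    if len(codons1) != len(codons2):
        raise ValueError("codon lists differ in length")
    n_codons = len(codons1)
    if n_codons < MIN_ALIGNED_CODONS:
        raise ValueError(f"only {n_codons} aligned codons (< {MIN_ALIGNED_CODONS})")
    S = sum(0.5 * (synonymous_sites(a) + synonymous_sites(b))
            for a, b in zip(codons1, codons2))
    N = 3.0 * n_codons - S
    sd = nd = 0.0
    for a, b in zip(codons1, codons2):
        ds, dn = pathway_differences(a, b)
        sd += ds
        nd += dn
    try:
        ks = jukes_cantor(sd / S) if S > 0 else None
    except SaturationError:
        logger.info("Ks saturated (ps=%.3f); pair excluded", sd / S)
        ks = None
    try:
        ka = jukes_cantor(nd / N) if N > 0 else None
    except SaturationError:
        ka = None
    return KsResult(ks=ks, ka=ka, n_codons=n_codons, s_sites=S, n_sites=N, sd=sd, nd=nd)


# ---------------------------------------------------------------------------
# protein and codon alignment
# ---------------------------------------------------------------------------

_LOCAL_ALIGNER: Align.PairwiseAligner | None = None


def align_protein_pair(p1: str, p2: str) -> tuple[str, str]:
    """Local (Smith-Waterman) protein alignment, BLOSUM62 open 11 / extend 1.

    Local mode trims non-homologous tails (e.g. the recruited coding sequence
    of chimeric duplicates) so they cannot leak into the Ks columns.
    """
    global _LOCAL_ALIGNER
    if _LOCAL_ALIGNER is None:
        _LOCAL_ALIGNER = Align.PairwiseAligner()
        _LOCAL_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
        _LOCAL_ALIGNER.open_gap_score = -11.0
        _LOCAL_ALIGNER.extend_gap_score = -1.0
        _LOCAL_ALIGNER.mode = "local"
    aln = _LOCAL_ALIGNER.align(p1, p2)[0]
    return str(aln[0]), str(aln[1])


@dataclass(frozen=True)
class CodonAlignment:
    """Two CDS rows aligned codon-wise following a protein alignment profile."""
    id1: str
    id2: str
    row1: tuple[str, ...]   # codons or '---'
    row2: tuple[str, ...]
    protein_row1: str
    protein_row2: str

    def ungapped_codon_pairs(self) -> tuple[list[str], list[str]]:
        """Columns without gaps or stop codons, ready for NG86."""
        c1, c2 = [], []
        for a, b in zip(self.row1, self.row2):
            if "-" in a or "-" in b or a in STOP_CODONS or b in STOP_CODONS:
                continue
            c1.append(a)
            c2.append(b)
        return c1, c2


def codon_align_from_protein(
    aligned1: str, aligned2: str, cds1: str, cds2: str,
    id1: str = "seq1", id2: str = "seq2",
) -> CodonAlignment:
    """Back-translate a protein alignment onto the source CDSs.

    Each amino-acid column maps to its source codon; a protein gap becomes a
    3-nt gap.  The aligned proteins may be a local alignment (substrings of
    the full translations); codons are located accordingly.  Raises
    :class:`ConsistencyError` if a protein row is not found in its CDS
    translation.
    """
    rows = []
    for aligned, cds, name in ((aligned1, cds1, id1), (aligned2, cds2, id2)):
        prot_full = translate_cds(cds)
        segment = aligned.replace("-", "")
        offset = prot_full.find(segment)
        if offset < 0:
            pos = _first_mismatch(prot_full, segment)
            raise ConsistencyError(
                f"{name}: aligned protein does not match CDS translation "
                f"(first mismatch near residue {pos})")
        row = []
        i = offset
        for aa in aligned:
            if aa == "-":
                row.append("---")
            else:
                codon = cds[3 * i:3 * i + 3]
                if CODON_TO_AA.get(codon) != aa:
                    raise ConsistencyError(
                        f"{name}: residue {i} is {aa} but codon {codon} "
                        f"translates to {CODON_TO_AA.get(codon)}")
                row.append(codon)
                i += 1
        rows.append(tuple(row))
    return CodonAlignment(id1=id1, id2=id2, row1=rows[0], row2=rows[1],
                          protein_row1=aligned1, protein_row2=aligned2)


def _first_mismatch(full: str, segment: str) -> int:
    for i, (a, b) in enumerate(zip(full, segment)):
        if a != b:
            return i
    return min(len(full), len(segment))


def estimate_ks_ng86(alignment: CodonAlignment) -> KsResult:
    """NG86 Ks (and Ka) of a codon alignment; gap and stop columns dropped."""
    c1, c2 = alignment.ungapped_codon_pairs()
    return ng86_from_codons(c1, c2)


def ks_between_cds(cds1: str, cds2: str, id1: str = "seq1", id2: str = "seq2") -> KsResult:
    """Convenience: protein-align two CDSs and estimate NG86 Ks."""
    a1, a2 = align_protein_pair(translate_cds(cds1), translate_cds(cds2))
    return estimate_ks_ng86(codon_align_from_protein(a1, a2, cds1, cds2, id1, id2))


# ---------------------------------------------------------------------------
# pair records and filters
# ---------------------------------------------------------------------------

@dataclass
class ParalogPair:
    gene1: str
    gene2: str
    ks: float | None = None
    ka: float | None = None
    n_codons: int = 0
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.gene2 < self.gene1:
            self.gene1, self.gene2 = self.gene2, self.gene1

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene1, self.gene2))


@dataclass
class LinkedSet:
    id: str
    members: list[ParalogPair]

    @property
    def ks(self) -> float:
        """Arithmetic mean of member Ks values (the set's single age)."""
        vals = [p.ks for p in self.members if p.ks is not None]
        return float(np.mean(vals))

    @property
    def representative(self) -> ParalogPair:
        return min(self.members, key=lambda p: (p.gene1, p.gene2))


def filter_young_pairs(pairs: Iterable[ParalogPair], ks_max: float = 0.1) -> list[ParalogPair]:
    """Keep pairs with defined Ks <= ks_max (inclusive); drop saturated pairs."""
    kept = []
    for p in pairs:
        if p.ks is None:
            logger.info("pair %s-%s dropped: Ks undefined (saturation)", p.gene1, p.gene2)
        elif p.ks <= ks_max:
            kept.append(p)
    return kept


def remove_same_location_pairs(
    pairs: Iterable[ParalogPair], genes: Mapping[str, GeneModel]
) -> tuple[list[ParalogPair], list[ParalogPair]]:
    """Drop pairs whose genes share a chromosome and an identical coding
    extent: two names for one locus, an annotation artifact."""
    kept, removed = [], []
    for p in pairs:
        g1, g2 = genes[p.gene1], genes[p.gene2]
        same = (g1.chrom == g2.chrom and g1.coding_extent == g2.coding_extent)
        if same:
            p.flags.add("same_location")
            removed.append(p)
        else:
            kept.append(p)
    return kept, removed


# ---------------------------------------------------------------------------
# UPGMA shadow-pair removal
# ---------------------------------------------------------------------------

def select_representative_pairs(
    members: Sequence[str], ks_lookup: Mapping[frozenset[str], float | None]
) -> tuple[list[frozenset[str]], list[frozenset[str]], str]:
    """UPGMA-based choice of n-1 representative pairs in an n-member family.

    A family of n genes arose through n-1 duplication events, but all-vs-all
    similarity yields C(n,2) pairs.  A UPGMA tree is built from the pairwise
    Ks matrix; each internal node contributes the minimum-Ks gene pair
    spanning its two joined clusters (ties broken lexicographically).  The
    remaining pairs are shadows.  Returns (retained, shadows, newick).
    """
    members = sorted(members)
    n = len(members)
    if n < 2:
        return [], [], ""
    if n == 2:
        pair = frozenset(members)
        return [pair], [], f"({members[0]},{members[1]});"

    defined = [v for v in ks_lookup.values() if v is not None]
    fill = max(defined) if defined else 1.0
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = ks_lookup.get(frozenset((members[i], members[j])))
            if v is None:
                logger.info("undefined Ks for %s-%s imputed as %.4g",
                            members[i], members[j], fill)
                v = fill
            dist[i, j] = dist[j, i] = v

    condensed = dist[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    retained: list[frozenset[str]] = []
    for step, (a, b, _h, _cnt) in enumerate(Z):
        ca, cb = clusters.pop(int(a)), clusters.pop(int(b))
        best = min(
            ((dist[i, j], tuple(sorted((members[i], members[j]))))
             for i in ca for j in cb),
            key=lambda t: (t[0], t[1]),
        )
        retained.append(frozenset(best[1]))
        clusters[n + step] = ca + cb

    all_pairs = {frozenset((members[i], members[j]))
                 for i in range(n) for j in range(i + 1, n)}
    shadows = sorted(all_pairs - set(retained), key=sorted)
    return retained, shadows, _linkage_to_newick(Z, members)


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for step, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        la = (h - heights[a]) / 2.0
        lb = (h - heights[b]) / 2.0
        nodes[n + step] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + step] = h
    return nodes[n + len(Z) - 1] + ";"


def remove_shadow_pairs(
    pairs: list[ParalogPair], families: Iterable[frozenset[str]]
) -> tuple[list[ParalogPair], list[ParalogPair], dict[str, str]]:
    """Apply UPGMA representative selection family-by-family.

    ``families`` are member sets (only 3-5 member families have shadows).
    Returns (kept, shadows, newick per family-key).
    """
    by_key = {p.key: p for p in pairs}
    trees: dict[str, str] = {}
    shadow_keys: set[frozenset[str]] = set()
    for members in families:
        fam_pairs = {k: v.ks for k, v in by_key.items() if k <= members}
        if len(members) < 3 or not fam_pairs:
            continue
        retained, shadows, newick = select_representative_pairs(
            sorted(members), fam_pairs)
        trees["|".join(sorted(members))] = newick
        shadow_keys.update(k for k in shadows if k in by_key)
    kept, dropped = [], []
    for p in pairs:
        if p.key in shadow_keys:
            p.flags.add("shadow")
            dropped.append(p)
        else:
            kept.append(p)
    return kept, dropped, trees


# ---------------------------------------------------------------------------
# linked-set detection
# ---------------------------------------------------------------------------

def detect_linked_sets(
    pairs: Sequence[ParalogPair],
    genes: Mapping[str, GeneModel],
    max_intervening: int = 1,
) -> tuple[list[ParalogPair], list[LinkedSet]]:
    """Merge collinear neighboring pairs into linked sets.

    Pairs (A1,A2) and (B1,B2) merge when A1/B1 are neighbors (same
    chromosome, <= max_intervening genes apart) and A2/B2 are neighbors with
    the same relative order and strand relationship - the signature of one
    duplication copying a multi-gene segment.  Returns (unmerged pairs,
    linked sets); a set's Ks is the mean over members.
    """
    rank: dict[str, tuple[str, int]] = {}
    by_chrom: dict[str, list[str]] = {}
    for g in genes.values():
        if g.canonical_id is None or g.excluded:
            continue
        by_chrom.setdefault(g.chrom, []).append(g.id)
    for chrom, ids in by_chrom.items():
        ids.sort(key=lambda gid: (genes[gid].coding_extent[0], gid))
        for i, gid in enumerate(ids):
            rank[gid] = (chrom, i)

    max_step = max_intervening + 1

    def neighbors(x: str, y: str) -> int | None:
        cx, rx = rank[x]
        cy, ry = rank[y]
        if cx != cy or x == y:
            return None
        d = ry - rx
        return d if 0 < abs(d) <= max_step else None

    def mergeable(p: ParalogPair, q: ParalogPair) -> bool:
        for (a1, a2) in ((p.gene1, p.gene2), (p.gene2, p.gene1)):
            for (b1, b2) in ((q.gene1, q.gene2), (q.gene2, q.gene1)):
                d1 = neighbors(a1, b1)
                d2 = neighbors(a2, b2)
                if d1 is None or d2 is None:
                    continue
                rel_a = genes[a1].strand == genes[a2].strand
                rel_b = genes[b1].strand == genes[b2].strand
                if rel_a != rel_b:
                    continue
                collinear = (d1 * d2 > 0) if rel_a else (d1 * d2 < 0)
                if collinear:
                    return True
        return False

    idx_uf = list(range(len(pairs)))

    def find(i: int) -> int:
        while idx_uf[i] != i:
            idx_uf[i] = idx_uf[idx_uf[i]]
            i = idx_uf[i]
        return i

    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            if mergeable(pairs[i], pairs[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    idx_uf[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[ParalogPair]] = {}
    for i, p in enumerate(pairs):
        groups.setdefault(find(i), []).append(p)

    singles, sets_ = [], []
    k = 0
    for root in sorted(groups, key=lambda r: (groups[r][0].gene1, groups[r][0].gene2)):
        grp = groups[root]
        if len(grp) == 1:
            singles.append(grp[0])
        else:
            k += 1
            for p in grp:
                p.flags.add("member_of_linked_set")
            sets_.append(LinkedSet(id=f"linked{k:04d}",
                                   members=sorted(grp, key=lambda p: (p.gene1, p.gene2))))
    return singles, sets_


def write_pair_table(pairs: Iterable[ParalogPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tks\tka\tn_codons\tflags\n")
        for p in pairs:
            ks = "" if p.ks is None else f"{p.ks:.6f}"
            ka = "" if p.ka is None else f"{p.ka:.6f}"
            fh.write(f"{p.gene1}\t{p.gene2}\t{ks}\t{ka}\t{p.n_codons}\t"
                     f"{','.join(sorted(p.flags))}\n")
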