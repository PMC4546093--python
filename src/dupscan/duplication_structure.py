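"""Genomic-neighborhood alignment, duplication-tract delineation and event
classification (structure, mechanism, geography).

The two paralogs' neighborhoods (coding extent +/- 200 kb, widened to 800 kb
when a chain touches the window edge) are aligned with an exact k-mer
anchor-chain method: 31-mer anchors between the windows are merged along
diagonals into blocks (allowing strand inversion as a separate orientation),
and blocks are chained collinearly into candidate duplication tracts.  The
tract containing the focal gene pair yields the breakpoints and the
*duplication span* - the minimum of the two per-locus tract extents.

Classification is polarity-free (ancestral vs derived copy is not inferred):

* complete - both paralogs' CDS extents lie inside their tracts;
* partial  - exactly one CDS is truncated by a breakpoint (the other ORF
  lies wholly within the tract);
* chimeric - a breakpoint falls within a CDS on both loci, i.e. one ORF
  additionally recruits coding sequence from outside the duplicated tract.

Mechanism is RNA (retrotransposition) when one paralog's canonical
transcript is intronless while its partner has introns that are absent from
the intronless locus; a downstream poly-A tract is logged as supporting
evidence but not required.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .annotation_io import GeneModel, GenomeSequences, Interval

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 200_000
WIDE_FLANK = 800_000
DEFAULT_K = 31
MERGE_GAP = 300          # max gap between same-diagonal anchors within a block
MAX_CHAIN_GAP = 5_000    # max gap between chained blocks (both loci)
SPLICE_GAP = 50          # near-zero gap on one locus admits a spliced junction
CLASS_SLACK = 200        # bp tolerance for CDS-inside-tract tests (anchor edge erosion)
MAX_KMER_OCC = 4


@dataclass(frozen=True)
class AlignmentBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str          # '+' direct, '-' inverted
    identity: float      # percent

    @property
    def a_len(self) -> int:
        return self.a_end - self.a_start


@dataclass
class AlignmentBlockSet:
    a_chrom: str
    a_window: Interval
    b_chrom: str
    b_window: Interval
    blocks: list[AlignmentBlock] = field(default_factory=list)
    flank: int = DEFAULT_FLANK

    @property
    def empty(self) -> bool:
        return not self.blocks


@dataclass(frozen=True)
class Tract:
    a_chrom: str
    a_interval: Interval
    b_chrom: str
    b_interval: Interval
    strand: str
    n_blocks: int

    @property
    def a_extent(self) -> int:
        return self.a_interval[1] - self.a_interval[0]

    @property
    def b_extent(self) -> int:
        return self.b_interval[1] - self.b_interval[0]

    @property
    def span(self) -> int:
        """Minimum duplication span: the smaller per-locus tract extent."""
        return min(self.a_extent, self.b_extent)

    @property
    def breakpoints(self) -> dict[str, Interval]:
        return {"a": self.a_interval, "b": self.b_interval}


@dataclass
class DuplicationEvent:
    event_id: str
    gene1: str
    gene2: str
    members: tuple[tuple[str, str], ...] = ()
    ks: float | None = None
    structural_class: str | None = None     # complete | partial | chimeric (DNA only)
    mechanism: str | None = None            # DNA | RNA
    location: str | None = None             # intrachromosomal | interchromosomal | unassigned
    orientation: str | None = None          # direct | inverse | n/a
    span: int | None = None
    distance: int | None = None
    conversion: bool | None = None
    conversion_tested: bool = False
    cohort: str | None = None
    chrom1: str | None = None
    chrom2: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def category(self) -> str | None:
        """Reporting category: structural class for DNA events, 'retro' for RNA."""
        if self.mechanism == "RNA":
            return "retro"
        return self.structural_class

    @property
    def linked(self) -> bool:
        return len(self.members) > 1


# ---------------------------------------------------------------------------
# anchor-chain alignment
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i


def _pack_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-packed k-mers (k <= 32) and their positions; windows containing
    non-ACGT characters are dropped."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for t in range(k):
        window = codes[t:t + n]
        valid &= window != 255
        h |= (window & np.uint8(3)).astype(np.uint64) << np.uint64(2 * t)
    pos = np.flatnonzero(valid)
    return h[pos], pos


def _kmer_anchors(seq_a: str, seq_b: str, k: int,
                  max_occ: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions (ia, ib) of exact shared k-mers between two windows."""
    ha, pa = _pack_kmers(seq_a, k)
    hb, pb = _pack_kmers(seq_b, k)
    if len(ha) == 0 or len(hb) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(ha, kind="stable")
    sorted_ha = ha[order]
    lo = np.searchsorted(sorted_ha, hb, side="left")
    hi = np.searchsorted(sorted_ha, hb, side="right")
    counts = hi - lo
    mask = (counts > 0) & (counts <= max_occ)
    c = counts[mask]
    if c.sum() == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = lo[mask]
    flat = np.repeat(starts, c) + np.arange(c.sum()) - np.repeat(np.cumsum(c) - c, c)
    ia = pa[order[flat]]
    ib = np.repeat(pb[mask], c)
    return ia, ib


def _merge_diagonal(anchors: tuple[np.ndarray, np.ndarray], k: int,
                    merge_gap: int) -> list[tuple[int, int, int, int]]:
    """Group same-diagonal anchors into blocks (local coords)."""
    ia, ib = anchors
    if len(ia) == 0:
        return []
    diag = ia - ib
    order = np.lexsort((ia, diag))
    d, a = diag[order], ia[order]
    new_block = np.ones(len(a), dtype=bool)
    new_block[1:] = (d[1:] != d[:-1]) | (a[1:] - (a[:-1] + k) > merge_gap)
    starts = np.flatnonzero(new_block)
    ends = np.append(starts[1:], len(a))
    blocks = []
    for s, e in zip(starts, ends):
        a0, a1 = int(a[s]), int(a[e - 1]) + k
        blocks.append((a0, a1, a0 - int(d[s]), a1 - int(d[s])))
    return blocks


def _block_identity(seq_a: str, seq_b_oriented: str, a0: int, a1: int, b0: int, b1: int) -> float:
    sa = seq_a[a0:a1]
    sb = seq_b_oriented[b0:b1]
    n = min(len(sa), len(sb))
    if n == 0:
        return 0.0
    matches = sum(1 for x, y in zip(sa[:n], sb[:n]) if x == y)
    return 100.0 * matches / n


def align_genomic_neighborhoods(
    gene_a: GeneModel,
    gene_b: GeneModel,
    genome: GenomeSequences,
    flank: int = DEFAULT_FLANK,
    k: int = DEFAULT_K,
    merge_gap: int = MERGE_GAP,
    max_kmer_occ: int = MAX_KMER_OCC,
) -> AlignmentBlockSet:
    """Anchor-chain alignment of the two paralogs' genomic neighborhoods.

    Windows are the coding extents padded by ``flank`` and clipped at
    chromosome ends.  Both orientations are scanned; trivial self-matches of
    overlapping windows on one chromosome (genomic diagonal zero) are
    discarded.  An empty block set marks the pair unalignable.
    """
    lengths = genome.lengths
    a_lo, a_hi = gene_a.coding_extent
    b_lo, b_hi = gene_b.coding_extent
    wa: Interval = (max(0, a_lo - flank), min(lengths[gene_a.chrom], a_hi + flank))
    wb: Interval = (max(0, b_lo - flank), min(lengths[gene_b.chrom], b_hi + flank))
    seq_a = genome[gene_a.chrom][wa[0]:wa[1]]
    seq_b = genome[gene_b.chrom][wb[0]:wb[1]]

    out = AlignmentBlockSet(a_chrom=gene_a.chrom, a_window=wa,
                            b_chrom=gene_b.chrom, b_window=wb, flank=flank)
    same_chrom = gene_a.chrom == gene_b.chrom

    # direct orientation
    for a0, a1, b0, b1 in _merge_diagonal(
            _kmer_anchors(seq_a, seq_b, k, max_kmer_occ), k, merge_gap):
        ga = (wa[0] + a0, wa[0] + a1)
        gb = (wb[0] + b0, wb[0] + b1)
        if same_chrom and ga == gb:
            continue  # window-overlap self-match
        ident = _block_identity(seq_a, seq_b, a0, a1, b0, b1)
        out.blocks.append(AlignmentBlock(*ga, *gb, "+", ident))

    # inverted orientation: scan against the reverse complement of window B
    seq_b_rc = _revcomp(seq_b)
    len_b = len(seq_b)
    for a0, a1, b0_rc, b1_rc in _merge_diagonal(
            _kmer_anchors(seq_a, seq_b_rc, k, max_kmer_occ), k, merge_gap):
        gb = (wb[0] + len_b - b1_rc, wb[0] + len_b - b0_rc)
        ga = (wa[0] + a0, wa[0] + a1)
        ident = _block_identity(seq_a, seq_b_rc, a0, a1, b0_rc, b1_rc)
        out.blocks.append(AlignmentBlock(*ga, *gb, "-", ident))

    out.blocks.sort(key=lambda b: (b.strand, b.a_start, b.b_start))
    if out.empty:
        logger.info("no anchors between %s and %s neighborhoods", gene_a.id, gene_b.id)
    return out


# ---------------------------------------------------------------------------
# tract delineation
# ---------------------------------------------------------------------------

def _chains(blocks: list[AlignmentBlock], strand: str, max_chain_gap: int,
            splice_gap: int, k: int) -> list[list[AlignmentBlock]]:
    """Greedy collinear chaining of same-orientation blocks.

    Adjacent blocks chain when the inter-block gap is <= max_chain_gap on
    both loci, or near zero on one locus (a spliced junction, as in
    retrogene insertions whose donor-side gaps are introns).
    """
    sel = sorted((b for b in blocks if b.strand == strand),
                 key=lambda b: (b.a_start, b.b_start))
    chains: list[list[AlignmentBlock]] = []
    for b in sel:
        placed = False
        for chain in chains:
            prev = chain[-1]
            gap_a = b.a_start - prev.a_end
            if strand == "+":
                gap_b = b.b_start - prev.b_end
            else:
                gap_b = prev.b_start - b.b_end
            if gap_a < -k or gap_b < -k:
                continue
            if (gap_a <= max_chain_gap and gap_b <= max_chain_gap) or \
                    min(gap_a, gap_b) <= splice_gap:
                chain.append(b)
                placed = True
                break
        if not placed:
            chains.append([b])
    return chains


def delineate_duplication_tract(
    blockset: AlignmentBlockSet,
    gene_a: GeneModel,
    gene_b: GeneModel,
    max_chain_gap: int = MAX_CHAIN_GAP,
    splice_gap: int = SPLICE_GAP,
    k: int = DEFAULT_K,
) -> Tract | None:
    """Maximal collinear chain containing the focal gene pair -> tract.

    Returns None (structure undetermined) when no chain overlaps both focal
    genes' coding extents.
    """
    if blockset.empty:
        return None
    ea = gene_a.coding_extent
    eb = gene_b.coding_extent
    best: tuple[int, Tract] | None = None
    for strand in "+-":
        for chain in _chains(blockset.blocks, strand, max_chain_gap, splice_gap, k):
            a_iv = (chain[0].a_start, chain[-1].a_end)
            b_iv = (min(b.b_start for b in chain), max(b.b_end for b in chain))
            if not (_overlap(a_iv, ea) and _overlap(b_iv, eb)):
                continue
            cover = sum(b.a_len for b in chain)
            tract = Tract(a_chrom=blockset.a_chrom, a_interval=a_iv,
                          b_chrom=blockset.b_chrom, b_interval=b_iv,
                          strand=strand, n_blocks=len(chain))
            if best is None or cover > best[0]:
                best = (cover, tract)
    return best[1] if best else None


def _overlap(x: Interval, y: Interval) -> bool:
    return x[0] < y[1] and y[0] < x[1]


def _touches_edge(tract: Tract, blockset: AlignmentBlockSet, margin: int) -> bool:
    (a0, a1), (b0, b1) = tract.a_interval, tract.b_interval
    wa, wb = blockset.a_window, blockset.b_window
    return (a0 - wa[0] <= margin or wa[1] - a1 <= margin or
            b0 - wb[0] <= margin or wb[1] - b1 <= margin)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_structure(
    tract: Tract | None,
    gene_a: GeneModel,
    gene_b: GeneModel,
    slack: int = CLASS_SLACK,
) -> str | None:
    """complete / partial / chimeric from CDS-vs-tract geometry (see module
    docstring); None when the tract is undetermined."""
    if tract is None:
        return None
    inside_a = _contained(gene_a.coding_extent, tract.a_interval, slack)
    inside_b = _contained(gene_b.coding_extent, tract.b_interval, slack)
    if inside_a and inside_b:
        return "complete"
    if inside_a or inside_b:
        return "partial"
    return "chimeric"


def _contained(inner: Interval, outer: Interval, slack: int) -> bool:
    return inner[0] >= outer[0] - slack and inner[1] <= outer[1] + slack


def classify_mechanism(
    gene_a: GeneModel,
    gene_b: GeneModel,
    blockset: AlignmentBlockSet | None,
    genome: GenomeSequences,
    intron_cover_max: float = 0.2,
    polya_len: int = 10,
    polya_window: int = 50,
) -> tuple[str, list[str]]:
    """(mechanism, notes): RNA iff one canonical transcript is intronless,
    the partner has introns, and those introns are absent (unaligned) at the
    intronless locus.  Both-single-exon pairs default to DNA (no intron-loss
    signal exists)."""
    ia = gene_a.canonical.n_introns
    ib = gene_b.canonical.n_introns
    notes: list[str] = []
    if (ia == 0) == (ib == 0):
        return "DNA", notes
    intronless, partner = (gene_a, gene_b) if ia == 0 else (gene_b, gene_a)
    partner_side = "b" if partner is gene_b else "a"
    introns = partner.canonical.introns
    total = sum(e - s for s, e in introns)
    covered = 0
    if blockset is not None and total > 0:
        for s, e in introns:
            for blk in blockset.blocks:
                bs, be = ((blk.b_start, blk.b_end) if partner_side == "b"
                          else (blk.a_start, blk.a_end))
                covered += max(0, min(e, be) - max(s, bs))
    frac = covered / total if total else 1.0
    if frac >= intron_cover_max:
        return "DNA", notes
    if _has_polya(intronless, genome, polya_len, polya_window):
        notes.append(f"polyA within {polya_window} bp downstream of {intronless.id}")
    notes.append(f"partner introns {100 * frac:.0f}% covered at {intronless.id} locus")
    return "RNA", notes


def _has_polya(gene: GeneModel, genome: GenomeSequences, run: int, window: int) -> bool:
    chrom = genome[gene.chrom]
    lo, hi = gene.coding_extent
    if gene.strand == "+":
        region = chrom[hi:hi + window + run]
        return "A" * run in region
    region = chrom[max(0, lo - window - run):lo]
    return "T" * run in region


def pair_geography(
    gene_a: GeneModel,
    gene_b: GeneModel,
    tract: Tract | None,
) -> tuple[str, str, int | None]:
    """(location, orientation, distance).

    Distance (intrachromosomal only) is the gap between the inner tract
    breakpoints, 0 when tracts touch or overlap; orientation is defined only
    for intrachromosomal pairs.
    """
    if gene_a.unassigned_location or gene_b.unassigned_location:
        return "unassigned", "n/a", None
    if gene_a.chrom != gene_b.chrom:
        return "interchromosomal", "n/a", None
    orientation = "direct" if gene_a.strand == gene_b.strand else "inverse"
    if tract is not None and tract.a_chrom == tract.b_chrom:
        iv1, iv2 = sorted([tract.a_interval, tract.b_interval])
    else:
        iv1, iv2 = sorted([gene_a.coding_extent, gene_b.coding_extent])
    distance = max(0, iv2[0] - iv1[1])
    return "intrachromosomal", orientation, distance


# ---------------------------------------------------------------------------
# per-event orchestration
# ---------------------------------------------------------------------------

def characterize_pair(
    gene_a: GeneModel,
    gene_b: GeneModel,
    genome: GenomeSequences,
    flank: int = DEFAULT_FLANK,
    wide_flank: int = WIDE_FLANK,
    k: int = DEFAULT_K,
    max_chain_gap: int = MAX_CHAIN_GAP,
    slack: int = CLASS_SLACK,
) -> tuple[Tract | None, AlignmentBlockSet, str | None, str, tuple[str, str, int | None], list[str]]:
    """Align neighborhoods, delineate the tract (auto-widening the flank when
    a chain touches the window edge), and classify one paralog pair.

    Returns (tract, blockset, structural_class, mechanism, geography, notes).
    """
    notes: list[str] = []
    blockset = align_genomic_neighborhoods(gene_a, gene_b, genome, flank=flank, k=k)
    tract = delineate_duplication_tract(blockset, gene_a, gene_b,
                                        max_chain_gap=max_chain_gap, k=k)
    if tract is not None and flank < wide_flank and _touches_edge(tract, blockset, k):
        notes.append(f"flank widened to {wide_flank}")
        blockset = align_genomic_neighborhoods(gene_a, gene_b, genome,
                                               flank=wide_flank, k=k)
        tract = delineate_duplication_tract(blockset, gene_a, gene_b,
                                            max_chain_gap=max_chain_gap, k=k)
    mechanism, mech_notes = classify_mechanism(gene_a, gene_b, blockset, genome)
    notes.extend(mech_notes)
    structure = None
    if mechanism == "DNA":
        structure = classify_structure(tract, gene_a, gene_b, slack=slack)
        if structure is None:
            notes.append("structure undetermined (no tract containing both genes)")
    geography = pair_geography(gene_a, gene_b, tract)
    return tract, blockset, structure, mechanism, geography, notes


def retro_span(gene_a: GeneModel, gene_b: GeneModel, tract: Tract | None) -> int | None:
    """Span for RNA-mediated events: the tract min-extent if delineated,
    else the intronless copy's coding extent (the mRNA footprint)."""
    if tract is not None:
        return tract.span
    intronless = gene_a if gene_a.canonical.n_introns == 0 else gene_b
    return intronless.coding_extent_length


def write_block_table(blockset: AlignmentBlockSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("chromA\tstartA\tendA\tchromB\tstartB\tendB\tstrand\tpident\n")
        for b in blockset.blocks:
            fh.write(f"{blockset.a_chrom}\t{b.a_start}\t{b.a_end}\t"
                     f"{blockset.b_chrom}\t{b.b_start}\t{b.b_end}\t{b.strand}\t"
                     f"{b.identity:.1f}\n")
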