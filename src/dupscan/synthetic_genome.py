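"""Truth-labelled synthetic genomes with planted gene-duplication events.

The simulator emulates the features of a mammalian-scale gene landscape that
the analysis depends on: multi-exon protein-coding genes whose coding extent
follows a lognormal law (median ~25 kb, mean ~65 kb), uniform-random
intergenic sequence (no repeats, keeping the anchor aligner's false-positive
rate negligible), and an outgroup lineage diverged at a configurable
synonymous distance (default Ks = 0.011, the human-chimp scale).

Duplication events are planted by copying a tract around a donor gene to a
new genomic location with controlled class (complete / partial / chimeric /
retro), placement (intra- or interchromosomal), transcriptional orientation
(direct / inverse), target synonymous divergence, flank divergence, and an
optional gene-conversion tract.  Background divergence of the derived copy
is generated by substitutions placed uniformly over the NG86 synonymous
sites until the pair's NG86 Ks first reaches the target - matching the
estimator's own model so that recovery tests are unconfounded.  Every event
yields a TruthRecord mirroring the pipeline's event table column-for-column,
so recovery scoring is a join.
"""
from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .annotation_io import GeneModel, GenomeSequences, Interval, Transcript
from .divergence_ks import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, ng86_from_codons

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("complete", "partial", "chimeric", "retro")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 5
    genes_per_chromosome: int = 24
    coding_extent_median: float = 25_000.0   # bp, lognormal median
    coding_extent_mean: float = 65_000.0     # bp, lognormal mean
    coding_extent_min: int = 6_000
    coding_extent_max: int = 300_000
    codons_min: int = 280
    codons_max: int = 600
    exons_min: int = 4
    exons_max: int = 8
    min_intron: int = 250
    gc: float = 0.41
    intergenic_min: int = 8_000
    intergenic_max: int = 40_000
    outgroup_ks: float = 0.011
    flank_divergence: float = 0.01
    chromosome_prefix: str = "chr"

    @property
    def extent_sigma(self) -> float:
        """Lognormal shape from the median/mean pair: mean = median e^(s^2/2)."""
        ratio = self.coding_extent_mean / self.coding_extent_median
        return float(np.sqrt(2.0 * np.log(ratio)))


@dataclass(frozen=True)
class EventSpec:
    event_class: str                     # complete | partial | chimeric | retro
    location: str = "intra"              # intra | inter
    orientation: str = "direct"          # direct | inverse
    target_ks: float = 0.0
    distance: int | None = None          # desired intra insertion distance (bp)
    conversion_tract: int | None = None  # planted conversion tract length (nt of CDS)
    flank_divergence: float | None = None

    def __post_init__(self):
        if self.event_class not in EVENT_CLASSES:
            raise SimulationError(f"unknown event class {self.event_class}")
        if not 0.0 <= self.target_ks <= 0.3:
            raise SimulationError(f"target Ks {self.target_ks} outside [0, 0.3]")


@dataclass
class TruthRecord:
    event_id: str
    spec: EventSpec
    donor_gene: str
    derived_gene: str
    donor_chrom: str
    donor_tract: Interval        # alignable tract at the donor locus
    derived_chrom: str
    derived_tract: Interval      # alignable tract at the derived locus
    span: int
    location: str                # intrachromosomal | interchromosomal
    orientation: str             # direct | inverse
    distance: int | None
    realized_ks: float
    converted: bool
    outgroup_ks: float

    @property
    def event_class(self) -> str:
        return self.spec.event_class

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.donor_gene, self.derived_gene))

    def _shift(self, chrom: str, pos: int, delta: int) -> None:
        def mv(iv: Interval) -> Interval:
            return (iv[0] + delta if iv[0] >= pos else iv[0],
                    iv[1] + delta if iv[1] > pos else iv[1])
        if self.donor_chrom == chrom:
            self.donor_tract = mv(self.donor_tract)
        if self.derived_chrom == chrom:
            self.derived_tract = mv(self.derived_tract)


@dataclass
class SyntheticStudy:
    genome: GenomeSequences
    genes: list[GeneModel]
    outgroup_genome: GenomeSequences
    outgroup_genes: list[GeneModel]
    truth: list[TruthRecord]
    centromeres: dict[str, Interval]
    config: SimConfig

    @property
    def gene_map(self) -> dict[str, GeneModel]:
        return {g.id: g for g in self.genes}


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_ACGT, size=n, p=p).tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 1) random sense codons + TAA; no internal stops."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx) + "TAA"


_SYN_CHANGES: dict[str, tuple[tuple[int, str], ...]] = {}


def synonymous_changes(codon: str) -> tuple[tuple[int, str], ...]:
    """Single-nucleotide synonymous changes available from a sense codon."""
    cached = _SYN_CHANGES.get(codon)
    if cached is None:
        aa = CODON_TO_AA[codon]
        cached = tuple(
            (pos, nt)
            for pos in range(3)
            for nt in "ACGT"
            if nt != codon[pos] and CODON_TO_AA[codon[:pos] + nt + codon[pos + 1:]] == aa
        )
        _SYN_CHANGES[codon] = cached
    return cached


def _codons(cds: str) -> list[str]:
    return [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]


# ---------------------------------------------------------------------------
# synonymous-divergence machinery
# ---------------------------------------------------------------------------

def mutate_to_target_ks(
    reference_codons: list[str],
    codons: list[str],
    target_ks: float,
    rng: np.random.Generator,
) -> tuple[list[str], float]:
    """Substitute at synonymous sites until NG86 Ks first reaches target.

    Sites are drawn uniformly over the available synonymous single-nucleotide
    changes (revisiting sites is allowed, as in a JC process restricted to
    synonymous positions).  Returns (mutated codons, realized Ks).
    """
    codons = list(codons)
    if target_ks <= 0:
        return codons, ng86_ks(reference_codons, codons)
    max_subs = 10 * len(codons) + 100
    for n_subs in range(max_subs):
        res = ng86_from_codons(reference_codons, codons)
        if res.ks is None:
            raise SimulationError(f"target Ks {target_ks} unreachable: saturation")
        if res.ks >= target_ks:
            return codons, res.ks
        weights = np.array([len(synonymous_changes(c)) for c in codons], dtype=float)
        total = weights.sum()
        if total == 0:
            raise SimulationError("no synonymous sites available")
        i = int(rng.choice(len(codons), p=weights / total))
        pos, nt = synonymous_changes(codons[i])[int(rng.integers(len(synonymous_changes(codons[i]))))]
        codons[i] = codons[i][:pos] + nt + codons[i][pos + 1:]
    raise SimulationError(f"target Ks {target_ks} not reached after {max_subs} substitutions")


def ng86_ks(c1: list[str], c2: list[str]) -> float:
    res = ng86_from_codons(c1, c2)
    if res.ks is None:
        raise SimulationError("Ks saturated")
    return res.ks


def evolve_synonymous_jc(
    codons: list[str], true_ks: float, rng: np.random.Generator
) -> list[str]:
    """Forward-simulate a Jukes-Cantor process confined to synonymous sites.

    The number of substitution events is Poisson(true_ks * S) where S is the
    NG86 synonymous site count of the starting sequence; events land
    uniformly on the currently synonymous changes (multiple hits allowed).
    This is the independent forward model used to measure estimator bias.
    """
    from .divergence_ks import synonymous_sites

    codons = list(codons)
    S = sum(synonymous_sites(c) for c in codons)
    n_events = int(rng.poisson(true_ks * S))
    for _ in range(n_events):
        weights = np.array([len(synonymous_changes(c)) for c in codons], dtype=float)
        i = int(rng.choice(len(codons), p=weights / weights.sum()))
        opts = synonymous_changes(codons[i])
        pos, nt = opts[int(rng.integers(len(opts)))]
        codons[i] = codons[i][:pos] + nt + codons[i][pos + 1:]
    return codons


def simulate_conversion_triplet(
    seed: int | np.random.Generator,
    n_sites: int = 1500,
    branch_divergence: float = 0.02,
    tract_length: int | None = None,
    shuffle_columns: bool = False,
):
    """Equidistant triplet (star topology) for gene-conversion experiments.

    Two paralogs and an outgroup each diverge from a common ancestor by
    ``branch_divergence`` per-site substitutions (so every pairwise distance
    is about twice the branch length).  ``tract_length`` overwrites a random
    window of paralog 2 with paralog 1 (a conversion positive);
    ``shuffle_columns=True`` then permutes the column order, destroying
    spatial clustering - the null used for type-I-error calibration.

    Returns (TripletAlignment, planted tract interval or None).
    """
    from .gene_conversion import TripletAlignment

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = rng.choice(list("ACGT"), size=n_sites)

    def mutate(seq: np.ndarray) -> np.ndarray:
        s = seq.copy()
        for i in np.flatnonzero(rng.random(n_sites) < branch_divergence):
            alternatives = [c for c in "ACGT" if c != s[i]]
            s[i] = alternatives[int(rng.integers(3))]
        return s

    p1, p2, out = mutate(anc), mutate(anc), mutate(anc)
    tract = None
    if tract_length:
        if tract_length > n_sites:
            raise SimulationError("conversion tract longer than the alignment")
        start = int(rng.integers(0, n_sites - tract_length + 1))
        p2[start:start + tract_length] = p1[start:start + tract_length]
        tract = (start, start + tract_length)
    if shuffle_columns:
        perm = rng.permutation(n_sites)
        p1, p2, out = p1[perm], p2[perm], out[perm]
        tract = None
    return (TripletAlignment(ids=("paralog1", "paralog2", "outgroup"),
                             rows=tuple("".join(x) for x in (p1, p2, out))),
            tract)


def apply_gene_conversion_tract(
    donor_cds: str, derived_cds: str, tract: Interval
) -> str:
    """Overwrite the derived copy's tract with the donor's current sequence.

    ``tract`` is a nucleotide interval on the aligned CDS region; outside the
    tract the derived copy is untouched.
    """
    s, e = tract
    limit = min(len(donor_cds), len(derived_cds))
    if not (0 <= s <= e <= limit):
        raise SimulationError(f"conversion tract {tract} outside aligned CDS (0..{limit})")
    return derived_cds[:s] + donor_cds[s:e] + derived_cds[e:]


# ---------------------------------------------------------------------------
# base genome
# ---------------------------------------------------------------------------

def sample_coding_extent(cfg: SimConfig, rng: np.random.Generator) -> int:
    """One draw from the lognormal coding-extent law (clipped to the
    configured bounds)."""
    extent = float(np.exp(np.log(cfg.coding_extent_median) +
                          cfg.extent_sigma * rng.standard_normal()))
    return int(np.clip(extent, cfg.coding_extent_min, cfg.coding_extent_max))


def _build_gene(
    rng: np.random.Generator, cfg: SimConfig, gene_id: str, chrom: str,
    offset: int, strand: str,
) -> tuple[GeneModel, str]:
    """One multi-exon fully coding gene; returns (model, genomic sequence)."""
    n_codons = int(rng.integers(cfg.codons_min, cfg.codons_max + 1))
    cds = _random_cds(rng, n_codons)
    n_exons = int(rng.integers(cfg.exons_min, cfg.exons_max + 1))
    extent = sample_coding_extent(cfg, rng)
    extent = max(extent, len(cds) + (n_exons - 1) * cfg.min_intron)

    # split the CDS into n_exons chunks of >= 60 nt
    while True:
        cuts = np.sort(rng.choice(np.arange(60, len(cds) - 59), size=n_exons - 1,
                                  replace=False))
        sizes = np.diff(np.concatenate([[0], cuts, [len(cds)]]))
        if sizes.min() >= 60:
            break
    intron_total = extent - len(cds)
    props = rng.dirichlet(np.ones(n_exons - 1)) if n_exons > 1 else np.array([])
    intron_sizes = (cfg.min_intron +
                    (props * (intron_total - cfg.min_intron * (n_exons - 1))).astype(int)
                    if n_exons > 1 else np.array([], dtype=int))

    pieces, intervals = [], []
    pos = 0
    cds_pos = 0
    for i, size in enumerate(sizes):
        pieces.append(cds[cds_pos:cds_pos + size])
        intervals.append((pos, pos + int(size)))
        pos += int(size)
        cds_pos += int(size)
        if i < n_exons - 1:
            pieces.append(_random_seq(rng, int(intron_sizes[i]), cfg.gc))
            pos += int(intron_sizes[i])
    region = "".join(pieces)

    if strand == "-":
        L = len(region)
        region = str(Seq(region).reverse_complement())
        intervals = [(L - e, L - s) for s, e in reversed(intervals)]

    genomic = [(offset + s, offset + e) for s, e in intervals]
    tx = Transcript(id=f"{gene_id}.t1", exons=list(genomic), cds=list(genomic))
    gene = GeneModel(id=gene_id, chrom=chrom, strand=strand,
                     transcripts={tx.id: tx})
    return gene, region


def simulate_genome(
    config: SimConfig, seed: int | np.random.Generator
) -> tuple[GenomeSequences, list[GeneModel]]:
    """Deterministic multi-chromosome genome with non-overlapping genes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    genes: list[GeneModel] = []
    gid = 0
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"{config.chromosome_prefix}{c}"
        parts = []
        pos = 0
        for _ in range(config.genes_per_chromosome):
            gap = int(rng.integers(config.intergenic_min, config.intergenic_max + 1))
            parts.append(_random_seq(rng, gap, config.gc))
            pos += gap
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene, region = _build_gene(rng, config, f"gene{gid:04d}", chrom, pos, strand)
            parts.append(region)
            pos += len(region)
            genes.append(gene)
        parts.append(_random_seq(rng, int(rng.integers(config.intergenic_min,
                                                       config.intergenic_max + 1)),
                                 config.gc))
        seqs[chrom] = "".join(parts)
    return GenomeSequences(seqs), genes


# ---------------------------------------------------------------------------
# CDS read/write against the genome
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic position of every CDS nucleotide, in mRNA (reading) order."""
    flat = [p for s, e in gene.canonical_or_first().cds for p in range(s, e)]
    return flat[::-1] if gene.strand == "-" else flat


def _read_cds(seqs: dict[str, str], gene: GeneModel) -> str:
    chrom = seqs[gene.chrom]
    out = [chrom[p] for p in _cds_positions(gene)]
    s = "".join(out)
    return s.translate(_COMPLEMENT) if gene.strand == "-" else s


def _write_cds(seqs: dict[str, str], gene: GeneModel, new_cds: str) -> None:
    positions = _cds_positions(gene)
    if len(positions) != len(new_cds):
        raise SimulationError("CDS length mismatch on write-back")
    if gene.strand == "-":
        new_cds = new_cds.translate(_COMPLEMENT)
    arr = bytearray(seqs[gene.chrom], "ascii")
    for p, ch in zip(positions, new_cds.encode()):
        arr[p] = ch
    seqs[gene.chrom] = arr.decode()


def _canonical_or_first(gene: GeneModel) -> Transcript:
    if gene.canonical_id is not None:
        return gene.transcripts[gene.canonical_id]
    return gene.transcripts[sorted(gene.transcripts)[0]]


# the simulator works before canonical selection has run
GeneModel.canonical_or_first = _canonical_or_first  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# event planting
# ---------------------------------------------------------------------------

@dataclass
class _PlantState:
    seqs: dict[str, str]
    genes: list[GeneModel]
    reserved: dict[str, list[Interval]]
    used: set[str] = field(default_factory=set)
    next_gene: int = 10_000

    def gene_map(self) -> dict[str, GeneModel]:
        return {g.id: g for g in self.genes}


def _gene_extent(gene: GeneModel) -> Interval:
    tx = gene.canonical_or_first()
    return (tx.cds[0][0], tx.cds[-1][1])


def _free_points(state: _PlantState, chrom: str, margin: int = 2_000) -> list[Interval]:
    """Intergenic, non-reserved intervals where a fragment may be inserted."""
    blocked = [(max(0, s - margin), e + margin)
               for g in state.genes if g.chrom == chrom
               for s, e in [_gene_extent(g)]]
    blocked += [(max(0, s - margin), e + margin)
                for s, e in state.reserved.get(chrom, [])]
    blocked.sort()
    free = []
    pos = margin
    end = len(state.seqs[chrom]) - margin
    for s, e in blocked:
        if s > pos:
            free.append((pos, s))
        pos = max(pos, e)
    if pos < end:
        free.append((pos, end))
    return [iv for iv in free if iv[1] > iv[0]]


def _choose_insertion(state: _PlantState, chrom: str, desired: int | None,
                      rng: np.random.Generator) -> int:
    free = _free_points(state, chrom, margin=2_000)
    if not free:
        raise SimulationError(f"no insertion space left on {chrom}")
    if desired is None:
        lo, hi = free[int(rng.integers(len(free)))]
        return int(rng.integers(lo, hi))
    best = min(free, key=lambda iv: 0 if iv[0] <= desired < iv[1]
               else min(abs(desired - iv[0]), abs(desired - iv[1] + 1)))
    return int(np.clip(desired, best[0], best[1] - 1))


def _shift_all(state: _PlantState, truth: list[TruthRecord], chrom: str,
               pos: int, delta: int) -> None:
    for g in state.genes:
        if g.chrom == chrom:
            g.shift(pos, delta)
    state.reserved[chrom] = [
        (s + delta if s >= pos else s, e + delta if e > pos else e)
        for s, e in state.reserved.get(chrom, [])
    ]
    for t in truth:
        t._shift(chrom, pos, delta)


def _cut_position(gene: GeneModel, rng: np.random.Generator) -> tuple[int, int]:
    """(cds nucleotide offset, genomic position) of a codon-boundary cut that
    truncates the ORF inside an internal exon ('+' strand donors only)."""
    tx = gene.canonical_or_first()
    total = sum(e - s for s, e in tx.cds)
    lo_codon = max(150, total // 6 // 3)
    hi_codon = (total // 3) - 60
    if hi_codon <= lo_codon:
        raise SimulationError(f"gene {gene.id} too short to truncate")
    cut_codon = int(rng.integers(lo_codon, hi_codon))
    cut_nt = 3 * cut_codon
    walked = 0
    for s, e in tx.cds:
        if walked + (e - s) > cut_nt:
            return cut_nt, s + (cut_nt - walked)
        walked += e - s
    raise SimulationError("cut beyond CDS")


def plant_duplication_event(
    state: _PlantState,
    truth: list[TruthRecord],
    spec: EventSpec,
    cfg: SimConfig,
    rng: np.random.Generator,
    donor: GeneModel | None = None,
) -> TruthRecord:
    """Copy a tract around a compatible donor gene to a new location.

    Updates the genome, annotation, reserved intervals and truth list in
    place and returns the new TruthRecord.
    """
    donor = donor or _pick_donor(state, spec, rng)
    chrom_len = len(state.seqs[donor.chrom])
    ext = _gene_extent(donor)
    tx = donor.canonical_or_first()

    if spec.event_class in ("partial", "chimeric") and donor.strand != "+":
        raise SimulationError("partial/chimeric donors must be '+' strand")

    # --- build the inserted fragment and the derived transcript layout -----
    if spec.event_class == "complete":
        u = int(rng.integers(2_000, 8_000))
        d = int(rng.integers(2_000, 8_000))
        src = (max(0, ext[0] - u), min(chrom_len, ext[1] + d))
        frag = state.seqs[donor.chrom][src[0]:src[1]]
        rel_cds = [(s - src[0], e - src[0]) for s, e in tx.cds]
        align_len = len(frag)
        derived_strand = donor.strand
    elif spec.event_class in ("partial", "chimeric"):
        u = int(rng.integers(2_000, 8_000))
        cut_nt, cut_pos = _cut_position(donor, rng)
        src = (max(0, ext[0] - u), cut_pos)
        tract_copy = state.seqs[donor.chrom][src[0]:src[1]]
        rel_cds = [(max(0, s - src[0]), e - src[0])
                   for s, e in tx.cds if s < cut_pos]
        rel_cds = [(s, min(e, len(tract_copy))) for s, e in rel_cds]
        align_len = len(tract_copy)
        if spec.event_class == "chimeric":
            spacer1 = _random_seq(rng, 500, cfg.gc)
            n_novel = int(rng.integers(60, 120))
            novel_exon = "".join(
                SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_novel)
            ) + "TAA"
            spacer2 = _random_seq(rng, 300, cfg.gc)
            frag = tract_copy + spacer1 + novel_exon + spacer2
            ns = len(tract_copy) + len(spacer1)
            rel_cds.append((ns, ns + len(novel_exon)))
        else:
            frag = tract_copy
        derived_strand = "+"
    else:  # retro
        mrna = _read_cds(state.seqs, donor)
        spacer = _random_seq(rng, 8, cfg.gc)
        frag = mrna + spacer + "A" * 12 + _random_seq(rng, 30, cfg.gc)
        rel_cds = [(0, len(mrna))]
        align_len = len(mrna)
        derived_strand = "+"
        src = ext  # the donor-side alignable footprint

    align_rel: Interval = (0, align_len)
    # retro fragments are strand-collapsed mRNA copies: a '-' donor already
    # contributes an inverted relationship before any flip
    flip = spec.orientation == "inverse"
    if spec.event_class == "retro" and donor.strand == "-":
        flip = not flip
    if flip:
        L = len(frag)
        frag = str(Seq(frag).reverse_complement())
        rel_cds = [(L - e, L - s) for s, e in reversed(rel_cds)]
        align_rel = (L - align_rel[1], L - align_rel[0])
        derived_strand = "-" if derived_strand == "+" else "+"

    # --- choose target location and insert --------------------------------
    # reserve the donor tract first so no later insertion can split it
    state.reserved.setdefault(donor.chrom, []).append(src)
    if spec.location == "intra":
        target_chrom = donor.chrom
        desired = None
        if spec.distance is not None:
            desired = src[1] + spec.distance
    else:
        others = [c for c in state.seqs if c != donor.chrom]
        target_chrom = others[int(rng.integers(len(others)))]
        desired = None
    p = _choose_insertion(state, target_chrom, desired, rng)

    state.seqs[target_chrom] = (state.seqs[target_chrom][:p] + frag +
                                state.seqs[target_chrom][p:])
    _shift_all(state, truth, target_chrom, p, len(frag))
    if target_chrom == donor.chrom and p <= src[0]:
        src = (src[0] + len(frag), src[1] + len(frag))

    state.next_gene += 1
    derived_id = f"gene{state.next_gene}"
    genomic_cds = [(p + s, p + e) for s, e in rel_cds]
    dtx = Transcript(id=f"{derived_id}.t1", exons=list(genomic_cds),
                     cds=list(genomic_cds))
    derived = GeneModel(id=derived_id, chrom=target_chrom, strand=derived_strand,
                        transcripts={dtx.id: dtx})
    state.genes.append(derived)
    state.used.update((donor.id, derived_id))
    state.reserved.setdefault(target_chrom, []).append((p, p + len(frag)))

    # --- mutations on the derived copy -------------------------------------
    donor_cds = _read_cds(state.seqs, donor)
    derived_cds = _read_cds(state.seqs, derived)
    n_hom = _homologous_codons(spec, donor_cds, derived_cds)
    donor_codons = _codons(donor_cds)[:n_hom]
    derived_codons = _codons(derived_cds)[:n_hom]
    derived_codons, realized = mutate_to_target_ks(
        donor_codons, derived_codons, spec.target_ks, rng)
    new_derived = "".join(derived_codons) + derived_cds[3 * n_hom:]

    if spec.conversion_tract:
        tract_len = min(spec.conversion_tract, 3 * n_hom)
        start = int(rng.integers(0, 3 * n_hom - tract_len + 1))
        new_derived = apply_gene_conversion_tract(
            donor_cds, new_derived, (start, start + tract_len))
        realized = ng86_ks(_codons(donor_cds)[:n_hom], _codons(new_derived)[:n_hom])
    _write_cds(state.seqs, derived, new_derived)

    fdiv = cfg.flank_divergence if spec.flank_divergence is None else spec.flank_divergence
    if fdiv > 0:
        _mutate_flanks(state, derived, (p, p + len(frag)), fdiv, rng)

    derived_tract = (p + align_rel[0], p + align_rel[1])
    location = ("intrachromosomal" if target_chrom == donor.chrom
                else "interchromosomal")
    distance = None
    if location == "intrachromosomal":
        iv1, iv2 = sorted([src, derived_tract])
        distance = max(0, iv2[0] - iv1[1])

    rec = TruthRecord(
        event_id=f"event{len(truth) + 1:04d}", spec=spec,
        donor_gene=donor.id, derived_gene=derived_id,
        donor_chrom=donor.chrom, donor_tract=src,
        derived_chrom=target_chrom, derived_tract=derived_tract,
        span=min(src[1] - src[0], align_rel[1] - align_rel[0]),
        location=location,
        orientation=("direct" if donor.strand == derived_strand else "inverse"),
        distance=distance, realized_ks=realized,
        converted=bool(spec.conversion_tract), outgroup_ks=cfg.outgroup_ks)
    truth.append(rec)
    return rec


def _homologous_codons(spec: EventSpec, donor_cds: str, derived_cds: str) -> int:
    """Codons shared by descent between donor and derived CDS (a prefix:
    the whole CDS for complete/retro, the pre-breakpoint part for
    partial/chimeric), excluding any terminal stop codon."""
    if spec.event_class in ("complete", "retro"):
        n = min(len(donor_cds), len(derived_cds)) // 3
    elif spec.event_class == "partial":
        n = len(derived_cds) // 3
    else:  # chimeric: exclude the recruited novel exon
        n = _shared_prefix_nt(donor_cds, derived_cds) // 3
    codons = _codons(derived_cds)[:n]
    while codons and codons[-1] in STOP_CODONS:
        codons.pop()
        n -= 1
    return n


def _shared_prefix_nt(donor_cds: str, derived_cds: str) -> int:
    n = min(len(donor_cds), len(derived_cds))
    i = 0
    while i < n and donor_cds[i] == derived_cds[i]:
        i += 1
    # round down to a codon boundary
    return 3 * (i // 3)


def _mutate_flanks(state: _PlantState, derived: GeneModel, frag_iv: Interval,
                   rate: float, rng: np.random.Generator) -> None:
    """Substitutions at the given per-site rate on inserted non-CDS bases."""
    chrom = state.seqs[derived.chrom]
    n = frag_iv[1] - frag_iv[0]
    mask = np.ones(n, dtype=bool)
    for s, e in derived.canonical_or_first().cds:
        mask[max(0, s - frag_iv[0]):max(0, e - frag_iv[0])] = False
    candidates = np.flatnonzero(mask) + frag_iv[0]
    if len(candidates) == 0:
        return
    hit = candidates[rng.random(len(candidates)) < rate]
    arr = bytearray(chrom, "ascii")
    for i in hit:
        current = arr[i]
        choices = [b for b in b"ACGT" if b != current]
        arr[i] = choices[int(rng.integers(3))]
    state.seqs[derived.chrom] = arr.decode()


def _pick_donor(state: _PlantState, spec: EventSpec,
                rng: np.random.Generator) -> GeneModel:
    def ok(g: GeneModel) -> bool:
        if g.id in state.used:
            return False
        tx = g.canonical_or_first()
        if spec.event_class in ("partial", "chimeric"):
            return g.strand == "+" and len(tx.cds) >= 3 and tx.cds_length >= 3 * 260
        if spec.event_class == "retro":
            return len(tx.cds) >= 2
        return True

    if spec.location == "inter" and len(state.seqs) < 2:
        raise SimulationError("interchromosomal event needs >= 2 chromosomes")
    candidates = [g for g in state.genes if ok(g)]
    if not candidates:
        raise SimulationError(
            f"no donor gene compatible with event class {spec.event_class}")
    return candidates[int(rng.integers(len(candidates)))]


# ---------------------------------------------------------------------------
# outgroup and full study assembly
# ---------------------------------------------------------------------------

def make_outgroup(
    genome: GenomeSequences, genes: list[GeneModel], outgroup_ks: float,
    rng: np.random.Generator,
) -> tuple[GenomeSequences, list[GeneModel]]:
    """Outgroup lineage: the pre-duplication genome with every gene's CDS
    diverged to the target synonymous distance."""
    seqs = {c: genome[c] for c in genome}
    out_genes = copy.deepcopy(genes)
    for gene in out_genes:
        cds = _read_cds(seqs, gene)
        codons = _codons(cds)
        sense = codons[:-1] if codons and codons[-1] in STOP_CODONS else codons
        mutated, _ = mutate_to_target_ks(list(sense), list(sense), outgroup_ks, rng)
        new_cds = "".join(mutated) + ("".join(codons[len(sense):]))
        _write_cds(seqs, gene, new_cds)
    return GenomeSequences(seqs), out_genes


def default_event_grid(ks_cycle: tuple[float, ...] = (0.0, 0.005, 0.01, 0.02, 0.05, 0.08),
                       n_per_combo: int = 6, n_retro: int = 6) -> list[EventSpec]:
    """The class x location x orientation grid used for recovery studies:
    3 DNA classes x {intra-direct, intra-inverse, inter} plus retro events."""
    specs: list[EventSpec] = []
    i = 0
    for cls in ("complete", "partial", "chimeric"):
        for loc, orient in (("intra", "direct"), ("intra", "inverse"), ("inter", "direct")):
            for _ in range(n_per_combo):
                specs.append(EventSpec(event_class=cls, location=loc,
                                       orientation=orient,
                                       target_ks=ks_cycle[i % len(ks_cycle)]))
                i += 1
    for j in range(n_retro):
        loc = "inter" if j % 3 else "intra"
        specs.append(EventSpec(event_class="retro", location=loc,
                               orientation="direct",
                               target_ks=ks_cycle[1 + j % (len(ks_cycle) - 1)]))
    return specs


def simulate_study(
    config: SimConfig,
    seed: int,
    specs: list[EventSpec] | None = None,
) -> SyntheticStudy:
    """Base genome + outgroup + planted events + centromere table."""
    rng = np.random.default_rng(seed)
    genome, genes = simulate_genome(config, rng)
    out_genome, out_genes = make_outgroup(genome, genes, config.outgroup_ks, rng)

    state = _PlantState(seqs={c: genome[c] for c in genome}, genes=genes,
                        reserved={})
    truth: list[TruthRecord] = []
    for spec in (specs if specs is not None else default_event_grid()):
        plant_duplication_event(state, truth, spec, config, rng)

    final = GenomeSequences(state.seqs)
    centromeres = {c: (int(0.45 * len(final[c])), int(0.45 * len(final[c])) + 100_000)
                   for c in final}
    return SyntheticStudy(genome=final, genes=state.genes,
                          outgroup_genome=out_genome, outgroup_genes=out_genes,
                          truth=truth, centromeres=centromeres, config=config)


def write_truth_table(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tgene1\tgene2\tks\tcategory\tlocation\torientation\t"
                 "span\tdistance\tconverted\n")
        for t in truth:
            g1, g2 = sorted((t.donor_gene, t.derived_gene))
            dist = "" if t.distance is None else t.distance
            fh.write(f"{t.event_id}\t{g1}\t{g2}\t{t.realized_ks:.6f}\t"
                     f"{t.event_class}\t{t.location}\t{t.orientation}\t{t.span}\t"
                     f"{dist}\t{t.converted}\n")


def write_centromere_table(centromeres: dict[str, Interval], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tcentromere_start\tcentromere_end\n")
        for c in sorted(centromeres):
            s, e = centromeres[c]
            fh.write(f"{c}\t{s}\t{e}\n")
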