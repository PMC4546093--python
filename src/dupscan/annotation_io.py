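"""Genome FASTA + GFF3 ingestion and canonical-transcript selection.

All coordinates are held internally as 0-based, half-open intervals on the
forward strand of the chromosome; GFF3's 1-based inclusive convention is
converted at the I/O boundary only.  A *gene* is represented by one or more
transcripts, each a sorted list of exon and CDS intervals; downstream stages
work exclusively with the canonical transcript, chosen as the transcript with
the largest summed CDS length (coding sequence, not genomic extent, because
the paralog search operates in protein space).
"""
from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: chromosome names matching this pattern are treated as unplaced scaffolds;
#: their genes are searched but excluded from geography statistics
SCAFFOLD_PATTERN = re.compile(r"scaffold|supercont|^GL|^KI", re.IGNORECASE)


class AnnotationError(ValueError):
    """Base class for annotation ingestion problems."""


class CoordinateError(AnnotationError):
    """A feature lies outside its chromosome."""


class FormatError(AnnotationError):
    """Structurally invalid GFF3 (e.g. a child feature without a parent)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class GenomeSequences(Mapping):
    """Chromosome name -> nucleotide string, with a consistent length map."""

    def __init__(self, sequences: Mapping[str, str]):
        bad = [n for n, s in sequences.items() if set(s) - set("ACGTN")]
        if bad:
            raise AnnotationError(f"non-ACGTN characters in sequences: {bad}")
        self._seqs = dict(sequences)

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def replace(self, name: str, seq: str) -> None:
        self._seqs[name] = seq


@dataclass
class Transcript:
    id: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def sort(self) -> None:
        self.exons.sort()
        self.cds.sort()

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)

    @property
    def introns(self) -> list[Interval]:
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)
                if ex[i + 1][0] > ex[i][1]]


@dataclass
class GeneModel:
    id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    canonical_id: str | None = None
    protein: str | None = None
    unassigned_location: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def canonical(self) -> Transcript:
        if self.canonical_id is None:
            raise AnnotationError(f"gene {self.id}: canonical transcript not selected")
        return self.transcripts[self.canonical_id]

    @property
    def coding_extent(self) -> Interval:
        """(first CDS start, last CDS end) of the canonical transcript."""
        cds = self.canonical.cds
        return (cds[0][0], cds[-1][1])

    @property
    def coding_extent_length(self) -> int:
        s, e = self.coding_extent
        return e - s

    def cds_sequence(self, genome: GenomeSequences) -> str:
        """Spliced CDS in reading-frame order (reverse-complemented on '-')."""
        chrom = genome[self.chrom]
        seq = "".join(chrom[s:e] for s, e in self.canonical.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def shift(self, pos: int, delta: int) -> None:
        """Shift all intervals at/after ``pos`` by ``delta`` (insertion upstream)."""
        def mv(iv: Interval) -> Interval:
            s, e = iv
            return (s + delta if s >= pos else s, e + delta if e > pos else e)

        for tx in self.transcripts.values():
            tx.exons = [mv(iv) for iv in tx.exons]
            tx.cds = [mv(iv) for iv in tx.cds]


def translate_cds(cds_seq: str) -> str:
    """Translate a CDS, dropping a trailing stop codon if present."""
    n = len(cds_seq) - len(cds_seq) % 3
    prot = str(Seq(cds_seq[:n]).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_genome_and_annotation(
    fasta_path: str | Path, gff3_path: str | Path
) -> tuple[GenomeSequences, list[GeneModel]]:
    """Read a genome FASTA plus GFF3 gene models into internal coordinates.

    GFF3 must provide gene / mRNA / exon / CDS features linked by ``Parent``
    attributes.  Raises :class:`CoordinateError` if a CDS exceeds its
    chromosome, :class:`FormatError` on missing parent links.
    """
    genome = GenomeSequences(
        {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    )
    genes = _parse_gff3(gff3_path)
    lengths = genome.lengths
    for gene in genes:
        if gene.chrom not in lengths:
            raise CoordinateError(f"gene {gene.id}: unknown chromosome {gene.chrom}")
        end = lengths[gene.chrom]
        for tx in gene.transcripts.values():
            tx.sort()
            for s, e in tx.cds:
                if s < 0 or e > end:
                    raise CoordinateError(
                        f"CDS of transcript {tx.id} (gene {gene.id}) at [{s},{e}) "
                        f"exceeds chromosome {gene.chrom} of length {end}"
                    )
        gene.unassigned_location = bool(SCAFFOLD_PATTERN.search(gene.chrom))
    return genome, genes


def _parse_gff3(gff3_path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: dict[str, GeneModel] = {}
    tx_to_gene: dict[str, str] = {}
    for f in db.features_of_type("gene"):
        genes[f.id] = GeneModel(id=f.id, chrom=f.seqid, strand=f.strand)
    for ftype in ("mRNA", "transcript"):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent")
            if not parents:
                raise FormatError(f"mRNA {f.id} has no Parent link")
            parent = parents[0]
            if parent not in genes:
                raise FormatError(f"mRNA {f.id} references unknown gene {parent}")
            genes[parent].transcripts[f.id] = Transcript(id=f.id)
            tx_to_gene[f.id] = parent
    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent")
            if not parents:
                raise FormatError(f"{ftype} at {f.seqid}:{f.start}-{f.end} has no Parent link")
            interval = (f.start - 1, f.end)  # 1-based inclusive -> 0-based half-open
            for parent in parents:
                gid = tx_to_gene.get(parent)
                if gid is None:
                    raise FormatError(f"{ftype} references unknown transcript {parent}")
                tx = genes[gid].transcripts[parent]
                (tx.exons if ftype == "exon" else tx.cds).append(interval)

    out = list(genes.values())
    for gene in out:
        for tx in gene.transcripts.values():
            tx.sort()
    return out


# ---------------------------------------------------------------------------
# canonical transcript selection
# ---------------------------------------------------------------------------

def select_canonical_transcripts(
    genes: Iterable[GeneModel], genome: GenomeSequences
) -> list[GeneModel]:
    """Pick the transcript with the largest total CDS length per gene.

    Ties break to the lexicographically smallest transcript id.  The derived
    protein (standard code, strand-aware) is attached.  Genes whose canonical
    CDS carries an internal stop codon or a length not divisible by 3 are
    flagged ``excluded`` with a logged warning and skipped by the search.
    """
    out = []
    for gene in genes:
        with_cds = [tx for tx in gene.transcripts.values() if tx.cds]
        if not with_cds:
            raise AnnotationError(f"gene {gene.id} has no transcript with CDS")
        best = min(with_cds, key=lambda tx: (-tx.cds_length, tx.id))
        gene.canonical_id = best.id
        cds_seq = gene.cds_sequence(genome)
        if len(cds_seq) % 3 != 0:
            logger.warning("gene %s: canonical CDS length %d not divisible by 3; excluded",
                           gene.id, len(cds_seq))
            gene.excluded, gene.exclusion_reason = True, "cds_length_not_multiple_of_3"
        else:
            prot = translate_cds(cds_seq)
            if "*" in prot:
                logger.warning("gene %s: internal stop codon in canonical CDS; excluded",
                               gene.id)
                gene.excluded, gene.exclusion_reason = True, "internal_stop"
            else:
                gene.protein = prot
        out.append(gene)
    return out


# ---------------------------------------------------------------------------
# writing (round-trip support and pipeline outputs)
# ---------------------------------------------------------------------------

def write_fasta(genome: GenomeSequences, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back out as GFF3 (1-based inclusive at the boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            spans = [iv for tx in gene.transcripts.values() for iv in tx.exons + tx.cds]
            gs = min(s for s, _ in spans)
            ge = max(e for _, e in spans)
            fh.write(_row(gene.chrom, "gene", gs, ge, gene.strand, f"ID={gene.id}"))
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                pieces = tx.exons + tx.cds
                ts = min(s for s, _ in pieces)
                te = max(e for _, e in pieces)
                fh.write(_row(gene.chrom, "mRNA", ts, te, gene.strand,
                              f"ID={tid};Parent={gene.id}"))
                for s, e in tx.exons:
                    fh.write(_row(gene.chrom, "exon", s, e, gene.strand, f"Parent={tid}"))
                for s, e in tx.cds:
                    fh.write(_row(gene.chrom, "CDS", s, e, gene.strand, f"Parent={tid}"))


def _row(chrom: str, ftype: str, start: int, end: int, strand: str, attrs: str) -> str:
    return f"{chrom}\tdupscan\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"


def write_canonical_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tcds_len\n")
        for gene in genes:
            if gene.canonical_id:
                fh.write(f"{gene.id}\t{gene.canonical_id}\t{gene.canonical.cds_length}\n")
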