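"""All-against-all protein similarity search and single-link gene families.

The search is a word-seeded local alignment: candidate pairs are screened by
shared 3-mer words with two word hits on a common diagonal (the classic
two-hit trigger), then scored by a full Smith-Waterman alignment under
BLOSUM62 with affine gaps (open 11, extend 1).  Expectation values follow the
Karlin-Altschul formula E = K m n exp(-lambda S) with the standard gapped
BLOSUM62(11,1) parameters.  Hits passing E <= 1e-10 and >= 40 % identity feed
single-link clustering; families of 2-5 members are the analysis substrate
(larger families are dropped, as the evolutionary dynamics of big multigene
families differ from those of young duplicates in small families).
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for gapped BLOSUM62, open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_WORD_SIZE = 3
DEFAULT_TWO_HIT_WINDOW = 100


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    bitscore: float
    evalue: float
    identity: float      # percent, 0-100, matches / alignment columns (incl. gaps)
    length: int          # alignment columns

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.query, self.subject))


@dataclass(frozen=True)
class GeneFamily:
    id: str
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


_ALIGNER: Align.PairwiseAligner | None = None


def _make_aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = Align.PairwiseAligner()
        _ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
        _ALIGNER.open_gap_score = -11.0
        _ALIGNER.extend_gap_score = -1.0
        _ALIGNER.mode = "local"
    return _ALIGNER


def local_alignment_stats(p1: str, p2: str) -> tuple[float, int, int]:
    """Best local alignment of two proteins -> (raw score, matches, columns)."""
    aligner = _make_aligner()
    try:
        aln = aligner.align(p1, p2)[0]
    except IndexError:
        return 0.0, 0, 0
    c = aln.counts()
    columns = c.identities + c.mismatches + c.internal_gaps
    return float(aln.score), c.identities, columns


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def expect_value(raw_score: float, query_len: int, db_residues: int) -> float:
    return KA_K * query_len * db_residues * math.exp(-KA_LAMBDA * raw_score)


def _two_hit_candidates(
    proteins: Mapping[str, str], word_size: int, window: int
) -> dict[frozenset[str], set[int]]:
    """Pairs with two non-overlapping shared words on one diagonal within
    ``window`` residues (the BLAST-style two-hit trigger).

    Returns pair -> the set of triggering diagonals (pos_in_first -
    pos_in_second under lexicographic name order), feeding the ungapped
    extension stage.
    """
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for name, seq in proteins.items():
        for i in range(len(seq) - word_size + 1):
            index[seq[i:i + word_size]].append((name, i))

    diag_hits: dict[tuple[str, str, int], list[int]] = defaultdict(list)
    for entries in index.values():
        if len(entries) < 2:
            continue
        for i, (na, pa) in enumerate(entries):
            for nb, pb in entries[i + 1:]:
                if na == nb:
                    continue
                if na < nb:
                    diag_hits[(na, nb, pa - pb)].append(pa)
                else:
                    diag_hits[(nb, na, pb - pa)].append(pb)

    candidates: dict[frozenset[str], set[int]] = defaultdict(set)
    for (na, nb, diag), positions in diag_hits.items():
        if len(positions) < 2:
            continue
        positions.sort()
        j = 0
        for i in range(len(positions)):
            while positions[i] - positions[j] > window:
                j += 1
            if positions[i] - positions[j] >= word_size:
                candidates[frozenset((na, nb))].add(diag)
                break
    return dict(candidates)


_AA = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = np.full(256, _AA.index("X"), dtype=np.int64)
for _i, _c in enumerate(_AA.encode()):
    _AA_INDEX[_c] = _i
_B62: np.ndarray | None = None


def _blosum_matrix() -> np.ndarray:
    global _B62
    if _B62 is None:
        m = substitution_matrices.load("BLOSUM62")
        _B62 = np.zeros((len(_AA), len(_AA)))
        for i, a in enumerate(_AA):
            for j, b in enumerate(_AA):
                _B62[i, j] = m[a][b]
    return _B62


def _encode(protein: str) -> np.ndarray:
    return _AA_INDEX[np.frombuffer(protein.encode(), dtype=np.uint8)]


def _best_ungapped_segment(ea: np.ndarray, eb: np.ndarray, diag: int) -> float:
    """Maximum-scoring ungapped segment on one diagonal (Kadane on BLOSUM62)."""
    if diag >= 0:
        sa = ea[diag:diag + len(eb)]
        sb = eb[:len(sa)]
    else:
        sb = eb[-diag:-diag + len(ea)]
        sa = ea[:len(sb)]
    if len(sa) == 0:
        return 0.0
    scores = _blosum_matrix()[sa, sb]
    c = np.cumsum(scores)
    running_min = np.minimum.accumulate(np.concatenate([[0.0], c]))[:-1]
    return float(np.max(c - running_min))


UNGAPPED_TRIGGER = 30.0   # raw BLOSUM62 score required on a triggered diagonal


def _passes_ungapped(p1: str, p2: str, diagonals: set[int],
                     threshold: float = UNGAPPED_TRIGGER) -> bool:
    ea, eb = _encode(p1), _encode(p2)
    return any(_best_ungapped_segment(ea, eb, d) >= threshold
               for d in sorted(diagonals))


def protein_similarity_search(
    proteins: Mapping[str, str],
    min_identity: float = 40.0,
    max_expect: float = 1e-10,
    word_size: int = DEFAULT_WORD_SIZE,
    two_hit_window: int = DEFAULT_TWO_HIT_WINDOW,
    exhaustive: bool = False,
) -> list[SimilarityHit]:
    """All-against-all search; returns deduplicated unordered pairs.

    ``exhaustive=True`` skips the word screen and aligns every pair (the
    dynamic-programming oracle mode used in tests).
    """
    proteins = {n: p for n, p in proteins.items() if p}
    short = [n for n, p in proteins.items() if len(p) < word_size]
    for name in short:
        logger.warning("protein %s shorter than word size %d: skipped", name, word_size)
        del proteins[name]

    names = sorted(proteins)
    db_residues = sum(len(p) for p in proteins.values())
    if exhaustive:
        candidates: dict[frozenset[str], set[int] | None] = {
            frozenset((a, b)): None
            for i, a in enumerate(names) for b in names[i + 1:]}
    else:
        candidates = _two_hit_candidates(proteins, word_size, two_hit_window)

    hits = []
    for pair in sorted(candidates, key=sorted):
        a, b = sorted(pair)
        diags = candidates[pair]
        if diags is not None and not _passes_ungapped(proteins[a], proteins[b], diags):
            continue
        score, matches, columns = local_alignment_stats(proteins[a], proteins[b])
        if columns == 0:
            continue
        ev = expect_value(score, min(len(proteins[a]), len(proteins[b])), db_residues)
        ident = 100.0 * matches / columns
        if ev <= max_expect and ident >= min_identity:
            hits.append(SimilarityHit(query=a, subject=b, bitscore=bit_score(score),
                                      evalue=ev, identity=ident, length=columns))
    return hits


def best_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    word_size: int = DEFAULT_WORD_SIZE,
    two_hit_window: int = DEFAULT_TWO_HIT_WINDOW,
    max_expect: float = 1e-5,
) -> dict[str, str]:
    """Best-scoring subject per query between two proteomes (e.g. the focal
    genes vs an outgroup proteome for ortholog assignment).

    Query and subject namespaces may overlap; only cross-set pairs are
    considered.  Queries without a hit at ``max_expect`` are absent from the
    returned mapping.
    """
    tagged = {f"q:{n}": p for n, p in queries.items() if len(p) >= word_size}
    tagged.update({f"s:{n}": p for n, p in subjects.items() if len(p) >= word_size})
    candidates = _two_hit_candidates(tagged, word_size, two_hit_window)
    db_residues = sum(len(p) for p in subjects.values())
    best: dict[str, tuple[float, str]] = {}
    for pair in sorted(candidates, key=sorted):
        a, b = sorted(pair)
        if a[0] == b[0]:
            continue  # same namespace
        q = a[2:] if a.startswith("q:") else b[2:]
        s = b[2:] if b.startswith("s:") else a[2:]
        if not _passes_ungapped(queries[q], subjects[s], candidates[pair]):
            continue
        score, _m, columns = local_alignment_stats(queries[q], subjects[s])
        if columns == 0:
            continue
        if expect_value(score, len(queries[q]), db_residues) > max_expect:
            continue
        if q not in best or score > best[q][0] or \
                (score == best[q][0] and s < best[q][1]):
            best[q] = (score, s)
    return {q: s for q, (_sc, s) in best.items()}


# ---------------------------------------------------------------------------
# single-link clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def add(self, x: str) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:  # deterministic root choice
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_families(
    hits: Iterable[SimilarityHit], all_genes: Iterable[str] | None = None
) -> list[GeneFamily]:
    """Connected components of the hit graph (single-link principle).

    If a protein A hits B and C, then A, B and C form one family regardless
    of the B-C similarity.  Genes listed in ``all_genes`` with no hits become
    singletons.
    """
    uf = _UnionFind()
    for hit in hits:
        uf.add(hit.query)
        uf.add(hit.subject)
        uf.union(hit.query, hit.subject)
    if all_genes is not None:
        for g in all_genes:
            uf.add(g)

    groups: dict[str, set[str]] = defaultdict(set)
    for g in uf.parent:
        groups[uf.find(g)].add(g)
    families = []
    for i, root in enumerate(sorted(groups, key=lambda r: min(groups[r])), 1):
        families.append(GeneFamily(id=f"fam{i:05d}", members=frozenset(groups[root])))
    return families


def filter_family_size(
    families: Iterable[GeneFamily], max_members: int = 5
) -> list[GeneFamily]:
    """Retain families with 2..max_members genes; log what was dropped."""
    kept = []
    for fam in families:
        if 2 <= fam.size <= max_members:
            kept.append(fam)
        elif fam.size > max_members:
            logger.info("family %s dropped: %d members > %d", fam.id, fam.size, max_members)
    return kept


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_hit_table(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject\tpident\tlength\tevalue\tbitscore\n")
        for h in hits:
            fh.write(f"{h.query}\t{h.subject}\t{h.identity:.2f}\t{h.length}\t"
                     f"{h.evalue:.3g}\t{h.bitscore:.1f}\n")


def read_hit_table(path: str | Path) -> list[SimilarityHit]:
    """Ingest a precomputed hit table (e.g. from an external search engine)."""
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            c = line.rstrip("\n").split("\t")
            hits.append(SimilarityHit(
                query=c[idx["query"]], subject=c[idx["subject"]],
                identity=float(c[idx["pident"]]), length=int(c[idx["length"]]),
                evalue=float(c[idx["evalue"]]), bitscore=float(c[idx["bitscore"]]),
            ))
    return hits


def write_family_table(families: Iterable[GeneFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tgene_id\n")
        for fam in families:
            for g in sorted(fam.members):
                fh.write(f"{fam.id}\t{g}\n")
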