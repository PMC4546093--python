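"""Ectopic gene-conversion screen: outgroup-anchored triplet alignment and a
Sawyer-style fragment permutation test.

Gene conversion between paralogs homogenizes a tract of sequence, resetting
apparent divergence inside the tract while the flanks keep diverging.  The
signature, viewed against an outgroup ortholog, is spatial clustering of the
alignment columns at which the two paralogs agree.  Following Sawyer's
approach, the triplet alignment is condensed to its polymorphic columns; the
observed statistic is the longest run of consecutive condensed columns at
which the paralogs match (no mismatches allowed inside a run, the gscale=0
analogue).  Randomly permuting the condensed column order destroys spatial
clustering but preserves the column composition, giving the null
distribution of the maximum run; the fragment p-value uses the add-one
estimator (1 + #{perm >= obs}) / (1 + n_perm), with a Bonferroni correction
across the candidate pairs tested within a family.
"""
from __future__ import annotations

import itertools
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .divergence_ks import align_protein_pair
from .annotation_io import translate_cds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TripletAlignment:
    """Aligned coding sequences of paralog 1, paralog 2 and an outgroup."""
    ids: tuple[str, str, str]
    rows: tuple[str, str, str]

    def __post_init__(self):
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("triplet rows differ in length")

    def polymorphic_columns(self) -> list[int]:
        """Columns with >= 2 distinct non-gap states."""
        out = []
        for j in range(len(self.rows[0])):
            states = {r[j] for r in self.rows if r[j] != "-"}
            if len(states) >= 2:
                out.append(j)
        return out

    def paralog_match_vector(self) -> tuple[np.ndarray, list[int]]:
        """Boolean match of the two paralogs over polymorphic columns."""
        cols = self.polymorphic_columns()
        r1, r2 = self.rows[0], self.rows[1]
        m = np.array([r1[j] == r2[j] and r1[j] != "-" and r2[j] != "-" for j in cols],
                     dtype=bool)
        return m, cols


@dataclass(frozen=True)
class Fragment:
    start: int          # alignment columns, half-open
    end: int
    score: int          # run length in condensed columns
    p_raw: float
    p_corrected: float
    significant: bool


@dataclass(frozen=True)
class ConversionResult:
    fragments: tuple[Fragment, ...]
    max_score: int
    p_value: float        # global (best-fragment) raw p
    p_corrected: float
    significant: bool
    n_perm: int
    seed: int | None
    n_polymorphic: int
    tested: bool = True
    notes: tuple[str, ...] = field(default_factory=tuple)


UNTESTED = ConversionResult(fragments=(), max_score=0, p_value=1.0, p_corrected=1.0,
                            significant=False, n_perm=0, seed=None, n_polymorphic=0,
                            tested=False, notes=("no outgroup ortholog",))


# ---------------------------------------------------------------------------
# triplet alignment construction
# ---------------------------------------------------------------------------

def build_triplet_alignment(
    cds1: str, cds2: str, cds_out: str,
    ids: tuple[str, str, str] = ("paralog1", "paralog2", "outgroup"),
) -> TripletAlignment:
    """Codon-aware triplet alignment anchored on paralog 1.

    The paralogs are first aligned locally in protein space, restricting the
    test to their homologous segment (a chimeric paralog's recruited tail is
    non-homologous sequence whose alignment columns would violate the
    permutation test's exchangeability assumption).  The outgroup is then
    aligned to paralog 1's segment semi-globally, the two alignments are
    merged on the shared row, and all rows are back-translated so every
    protein gap becomes a 3-nt gap.
    """
    p1, p2, po = (translate_cds(c) for c in (cds1, cds2, cds_out))
    a12 = align_protein_pair(p1, p2)
    seg1 = a12[0].replace("-", "")
    seg2 = a12[1].replace("-", "")
    off1 = p1.find(seg1)
    off2 = p2.find(seg2)
    a1o = _semiglobal(seg1, po)
    merged = _merge_on_center(a12, a1o)
    rows = tuple(_backtranslate(row, cds, off)
                 for row, cds, off in zip(merged, (cds1, cds2, cds_out),
                                          (off1, off2, 0)))
    return TripletAlignment(ids=ids, rows=rows)


_SEMIGLOBAL_ALIGNER = None


def _semiglobal(p1: str, p2: str) -> tuple[str, str]:
    global _SEMIGLOBAL_ALIGNER
    if _SEMIGLOBAL_ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
        aligner.mode = "global"
        _SEMIGLOBAL_ALIGNER = aligner
    aln = _SEMIGLOBAL_ALIGNER.align(p1, p2)[0]
    return str(aln[0]), str(aln[1])


def _merge_on_center(a12: tuple[str, str], a1o: tuple[str, str]) -> tuple[str, str, str]:
    """Merge two pairwise alignments sharing their first (center) sequence."""
    r1a, r2 = a12
    r1b, ro = a1o
    out1, out2, out3 = [], [], []
    i = j = 0
    while i < len(r1a) or j < len(r1b):
        ca = r1a[i] if i < len(r1a) else None
        cb = r1b[j] if j < len(r1b) else None
        if ca == "-" and (cb != "-" or cb is None):
            out1.append("-"); out2.append(r2[i]); out3.append("-")
            i += 1
        elif cb == "-" and (ca != "-" or ca is None):
            out1.append("-"); out2.append("-"); out3.append(ro[j])
            j += 1
        else:
            # both advance the center sequence (possibly both '-': emit both)
            if ca == "-" and cb == "-":
                out1.append("-"); out2.append(r2[i]); out3.append("-")
                i += 1
                continue
            out1.append(ca); out2.append(r2[i]); out3.append(ro[j])
            i += 1; j += 1
    return "".join(out1), "".join(out2), "".join(out3)


def _backtranslate(protein_row: str, cds: str, offset: int = 0) -> str:
    out = []
    i = offset
    for aa in protein_row:
        if aa == "-":
            out.append("---")
        else:
            out.append(cds[3 * i:3 * i + 3])
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _runs_of_true(m: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) half-open indices."""
    runs = []
    start = None
    for i, v in enumerate(m):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(m)))
    return runs


def _max_run(m: np.ndarray) -> int:
    best = run = 0
    for v in m:
        run = run + 1 if v else 0
        if run > best:
            best = run
    return best


def _null_max_runs_mc(m: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Max-run statistic under n_perm random permutations of column order."""
    L = len(m)
    # each row is an independent permutation of m
    mat = np.tile(m, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    best = np.zeros(n_perm, dtype=np.int64)
    run = np.zeros(n_perm, dtype=np.int64)
    for j in range(L):
        col = mat[:, j]
        run = (run + 1) * col
        np.maximum(best, run, out=best)
    return best


def exhaustive_null_max_runs(m: Sequence[bool]) -> list[int]:
    """Max-run statistic under every permutation of the columns (oracle)."""
    return [_max_run(np.array(perm, dtype=bool))
            for perm in itertools.permutations(list(m))]


def detect_gene_conversion(
    triplet: TripletAlignment,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    exhaustive: bool = False,
) -> ConversionResult:
    """Permutation test for conversion tracts between the two paralogs.

    With fewer than 2 polymorphic columns the alignment carries no signal and
    the result is p = 1 with no fragments.  ``exhaustive=True`` enumerates
    all column permutations (feasible for <= 8 polymorphic columns) instead
    of Monte-Carlo sampling.
    """
    m, cols = triplet.paralog_match_vector()
    n_poly = len(cols)
    if n_poly < 2:
        return ConversionResult(fragments=(), max_score=0, p_value=1.0,
                                p_corrected=1.0, significant=False, n_perm=0,
                                seed=seed, n_polymorphic=n_poly,
                                notes=("fewer than 2 polymorphic columns",))

    obs_runs = _runs_of_true(m)
    obs_max = max((e - s for s, e in obs_runs), default=0)

    if exhaustive:
        null = np.array(exhaustive_null_max_runs(m))
        n_eff = len(null)
    else:
        rng = np.random.default_rng(seed)
        null = _null_max_runs_mc(m, n_perm, rng)
        n_eff = n_perm

    def pval(score: int) -> float:
        return (1.0 + float(np.count_nonzero(null >= score))) / (1.0 + n_eff)

    fragments = []
    for s, e in obs_runs:
        score = e - s
        p_raw = pval(score)
        p_corr = min(1.0, p_raw * n_comparisons)
        fragments.append(Fragment(start=cols[s], end=cols[e - 1] + 1, score=score,
                                  p_raw=p_raw, p_corrected=p_corr,
                                  significant=p_corr <= alpha))
    fragments.sort(key=lambda f: (f.p_raw, -f.score, f.start))

    p_global = pval(obs_max) if obs_max > 0 else 1.0
    p_global_corr = min(1.0, p_global * n_comparisons)
    return ConversionResult(
        fragments=tuple(fragments), max_score=obs_max, p_value=p_global,
        p_corrected=p_global_corr, significant=p_global_corr <= alpha,
        n_perm=n_eff, seed=seed, n_polymorphic=n_poly)


def partition_by_conversion(
    event_ids: Sequence[str], results: dict[str, ConversionResult]
) -> tuple[list[str], list[str]]:
    """(all events, events without significant conversion).

    Events lacking an outgroup (untested) are retained in both sets.
    """
    all_events = list(event_ids)
    no_conv = [e for e in event_ids
               if not (results.get(e, UNTESTED).tested and results[e].significant)]
    return all_events, no_conv


def write_conversion_table(results: dict[str, ConversionResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tfrag_start\tfrag_end\tscore\tp_raw\tp_corrected\tsignificant\n")
        for eid in sorted(results):
            r = results[eid]
            if not r.fragments:
                fh.write(f"{eid}\t\t\t0\t{r.p_value:.4g}\t{r.p_corrected:.4g}\t"
                         f"{r.significant}\n")
            for f in r.fragments:
                fh.write(f"{eid}\t{f.start}\t{f.end}\t{f.score}\t{f.p_raw:.4g}\t"
                         f"{f.p_corrected:.4g}\t{f.significant}\n")
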