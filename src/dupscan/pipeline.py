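"""End-to-end orchestration: from genome + annotation to the event table and
the cohort-statistics report.

Stage order mirrors the survey design: canonical-transcript selection ->
all-vs-all protein search -> single-link families (<= 5 members) -> per-pair
codon alignment and NG86 Ks -> curation (same-location removal, UPGMA shadow
removal, linked-set merging) -> Ks <= 0.1 youth filter -> gene-conversion
screen against an outgroup -> tract delineation and event classification ->
cohort statistics on the {all, conversion-excluded} dataset variants.

A filter-accounting identity is verified on every run:
pairs_in = events' pairs + same-location removed + shadows removed
         + Ks-filtered + (merged pairs - linked sets formed ... implicitly
via member counting).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotation_io, cohort_statistics, divergence_ks, duplication_structure, \
    gene_conversion, homology_families
from .annotation_io import GeneModel, GenomeSequences
from .cohort_statistics import GTestResult
from .divergence_ks import LinkedSet, ParalogPair
from .duplication_structure import DuplicationEvent
from .gene_conversion import UNTESTED, ConversionResult

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    fasta: str | None = None
    gff3: str | None = None
    outgroup_fasta: str | None = None
    outgroup_gff3: str | None = None
    centromere_table: str | None = None
    out_dir: str = "dupscan_out"
    # search
    min_identity: float = 40.0
    max_expect: float = 1e-10
    # families / curation
    max_family_size: int = 5
    ks_max: float = 0.1
    max_intervening: int = 1
    # structure
    flank: int = 200_000
    wide_flank: int = 800_000
    anchor_k: int = 31
    max_chain_gap: int = 5_000
    # conversion
    n_perm: int = 10_000
    alpha: float = 0.05
    # misc
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


@dataclass
class PipelineResult:
    events: list[DuplicationEvent]
    pairs_all: list[ParalogPair]
    linked_sets: list[LinkedSet]
    conversion: dict[str, ConversionResult]
    statistics: dict
    counts: dict[str, float]
    genes: dict[str, GeneModel]
    trees: dict[str, str] = field(default_factory=dict)

    @property
    def no_conversion_event_ids(self) -> list[str]:
        ids = [e.event_id for e in self.events]
        _, keep = gene_conversion.partition_by_conversion(ids, self.conversion)
        return keep


# ---------------------------------------------------------------------------
# core analysis (in-memory)
# ---------------------------------------------------------------------------

def analyze(
    genome: GenomeSequences,
    genes: list[GeneModel],
    config: PipelineConfig | None = None,
    outgroup: tuple[GenomeSequences, list[GeneModel]] | None = None,
    centromeres: Mapping[str, tuple[int, int]] | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    counts: dict[str, float] = {}
    t0 = time.time()

    # stage 1: canonical transcripts and proteins
    genes = annotation_io.select_canonical_transcripts(genes, genome)
    gene_map = {g.id: g for g in genes}
    proteins = {g.id: g.protein for g in genes if not g.excluded and g.protein}
    counts["genes"] = len(genes)
    counts["genes_searched"] = len(proteins)
    _stage(counts, "canonical", t0)

    # stage 2: similarity search and families
    hits = homology_families.protein_similarity_search(
        proteins, min_identity=cfg.min_identity, max_expect=cfg.max_expect)
    families = homology_families.build_families(hits, all_genes=proteins)
    families = homology_families.filter_family_size(families,
                                                    max_members=cfg.max_family_size)
    counts["hits"] = len(hits)
    counts["families"] = len(families)
    _stage(counts, "families", t0)

    # stage 3: per-pair codon alignment + Ks
    pairs: list[ParalogPair] = []
    fam_of: dict[str, str] = {}
    for fam in families:
        members = sorted(fam.members)
        for g in members:
            fam_of[g] = fam.id
        for i, g1 in enumerate(members):
            for g2 in members[i + 1:]:
                pairs.append(_make_pair(g1, g2, gene_map, genome))
    counts["pairs_initial"] = len(pairs)

    # curation: same-location -> UPGMA shadows -> linked sets -> Ks filter
    pairs, same_loc = divergence_ks.remove_same_location_pairs(pairs, gene_map)
    counts["same_location_removed"] = len(same_loc)
    pairs, shadows, trees = divergence_ks.remove_shadow_pairs(
        pairs, [f.members for f in families])
    counts["shadow_removed"] = len(shadows)
    singles, linked = divergence_ks.detect_linked_sets(
        pairs, gene_map, max_intervening=cfg.max_intervening)
    counts["linked_sets"] = len(linked)
    counts["linked_member_pairs"] = sum(len(s.members) for s in linked)

    young_singles = divergence_ks.filter_young_pairs(singles, ks_max=cfg.ks_max)
    young_linked = [s for s in linked if s.ks <= cfg.ks_max]
    counts["ks_filtered"] = (len(singles) - len(young_singles) +
                             sum(len(s.members) for s in linked) -
                             sum(len(s.members) for s in young_linked))
    _stage(counts, "curation", t0)

    # accounting identity (member pairs conserved across filters)
    lhs = counts["pairs_initial"]
    rhs = (len(young_singles) + sum(len(s.members) for s in young_linked) +
           counts["same_location_removed"] + counts["shadow_removed"] +
           counts["ks_filtered"])
    if lhs != rhs:
        raise PipelineError(f"filter accounting broken: {lhs} pairs in, {rhs} accounted")

    # stage 4: event construction
    events: list[DuplicationEvent] = []
    event_members: dict[str, list[ParalogPair]] = {}
    items: list[tuple[ParalogPair | LinkedSet, bool]] = \
        [(p, False) for p in young_singles] + [(s, True) for s in young_linked]
    items.sort(key=lambda it: ((it[0].representative.gene1, it[0].representative.gene2)
                               if it[1] else (it[0].gene1, it[0].gene2)))
    for i, (item, is_set) in enumerate(items, 1):
        eid = f"event{i:04d}"
        if is_set:
            rep = item.representative
            ev = DuplicationEvent(event_id=eid, gene1=rep.gene1, gene2=rep.gene2,
                                  members=tuple((p.gene1, p.gene2) for p in item.members),
                                  ks=item.ks)
            event_members[eid] = list(item.members)
        else:
            ev = DuplicationEvent(event_id=eid, gene1=item.gene1, gene2=item.gene2,
                                  members=((item.gene1, item.gene2),), ks=item.ks)
            event_members[eid] = [item]
        events.append(ev)
    counts["events"] = len(events)

    # stage 5: gene-conversion screen
    retained_per_family: dict[str, int] = {}
    for ev in events:
        for g1, g2 in ev.members:
            fam = fam_of.get(g1)
            retained_per_family[fam] = retained_per_family.get(fam, 0) + 1
    conversion: dict[str, ConversionResult] = {}
    if outgroup is not None:
        out_genome, out_genes = outgroup
        out_genes = annotation_io.select_canonical_transcripts(out_genes, out_genome)
        out_map = {g.id: g for g in out_genes}
        out_prot = {g.id: g.protein for g in out_genes if not g.excluded and g.protein}
        best = homology_families.best_hits(proteins, out_prot)
        for ei, ev in enumerate(events):
            results = []
            for g1, g2 in ev.members:
                ortholog = best.get(g1) or best.get(g2)
                if ortholog is None:
                    continue
                triplet = gene_conversion.build_triplet_alignment(
                    gene_map[g1].cds_sequence(genome),
                    gene_map[g2].cds_sequence(genome),
                    out_map[ortholog].cds_sequence(out_genome),
                    ids=(g1, g2, ortholog))
                n_comp = max(1, retained_per_family.get(fam_of.get(g1), 1))
                results.append(gene_conversion.detect_gene_conversion(
                    triplet, n_perm=cfg.n_perm, seed=cfg.seed * 100_003 + ei,
                    alpha=cfg.alpha, n_comparisons=n_comp))
            if results:
                sig = [r for r in results if r.significant]
                conversion[ev.event_id] = sig[0] if sig else \
                    min(results, key=lambda r: r.p_corrected)
            else:
                conversion[ev.event_id] = UNTESTED
    else:
        conversion = {ev.event_id: UNTESTED for ev in events}
    for ev in events:
        res = conversion[ev.event_id]
        ev.conversion_tested = res.tested
        ev.conversion = res.significant if res.tested else None
    counts["conversion_significant"] = sum(
        1 for r in conversion.values() if r.tested and r.significant)
    _stage(counts, "conversion", t0)

    # stage 6: structure, mechanism, geography
    unalignable = 0
    for ev in events:
        ga, gb = gene_map[ev.gene1], gene_map[ev.gene2]
        tract, blockset, structure, mechanism, geo, notes = \
            duplication_structure.characterize_pair(
                ga, gb, genome, flank=cfg.flank, wide_flank=cfg.wide_flank,
                k=cfg.anchor_k, max_chain_gap=cfg.max_chain_gap)
        ev.mechanism = mechanism
        ev.structural_class = structure
        ev.location, ev.orientation, ev.distance = geo
        ev.chrom1, ev.chrom2 = ga.chrom, gb.chrom
        if mechanism == "RNA":
            ev.span = duplication_structure.retro_span(ga, gb, tract)
        elif tract is not None:
            ev.span = tract.span
        else:
            unalignable += 1
        ev.notes.extend(notes)
        if ev.ks is not None and ev.ks <= cfg.ks_max:
            ev.cohort = cohort_statistics.assign_cohort(ev.ks)
    counts["structure_undetermined"] = unalignable
    _stage(counts, "structure", t0)

    # stage 7: statistics on dataset variants
    statistics = compute_statistics(events, conversion, gene_map, centromeres)
    _stage(counts, "statistics", t0)

    return PipelineResult(events=events, pairs_all=pairs, linked_sets=linked,
                          conversion=conversion, statistics=statistics,
                          counts=counts, genes=gene_map, trees=trees)


def _make_pair(g1: str, g2: str, gene_map: Mapping[str, GeneModel],
               genome: GenomeSequences) -> ParalogPair:
    cds1 = gene_map[g1].cds_sequence(genome)
    cds2 = gene_map[g2].cds_sequence(genome)
    try:
        res = divergence_ks.ks_between_cds(cds1, cds2, g1, g2)
        return ParalogPair(gene1=g1, gene2=g2, ks=res.ks, ka=res.ka,
                           n_codons=res.n_codons)
    except ValueError as exc:
        logger.info("pair %s-%s: Ks undefined (%s)", g1, g2, exc)
        return ParalogPair(gene1=g1, gene2=g2, ks=None, ka=None, n_codons=0)


def _stage(counts: dict, name: str, t0: float) -> None:
    logger.info("stage %-12s done at %.1fs: %s", name, time.time() - t0,
                {k: v for k, v in counts.items()})


# ---------------------------------------------------------------------------
# statistics report
# ---------------------------------------------------------------------------

def _g(res: GTestResult | None) -> dict | None:
    if res is None:
        return None
    return {"G": res.g, "G_raw": res.g_raw, "q": res.q, "df": res.df, "p": res.p}


def compute_statistics(
    events: list[DuplicationEvent],
    conversion: dict[str, ConversionResult],
    gene_map: Mapping[str, GeneModel],
    centromeres: Mapping[str, tuple[int, int]] | None = None,
) -> dict:
    """Cohort / geography / structure statistics for the two dataset
    variants (all events; events without significant gene conversion)."""
    ids = [e.event_id for e in events]
    _, keep = gene_conversion.partition_by_conversion(ids, conversion)
    keep_set = set(keep)
    variants = {
        "all": events,
        "no_conversion": [e for e in events if e.event_id in keep_set],
    }
    genes_per_chrom: dict[str, int] = {}
    for g in gene_map.values():
        if g.canonical_id is not None and not g.excluded and not g.unassigned_location:
            genes_per_chrom[g.chrom] = genes_per_chrom.get(g.chrom, 0) + 1

    report: dict = {"n_events": len(events)}
    for name, evs in variants.items():
        located = [e for e in evs if e.location in ("intrachromosomal",
                                                    "interchromosomal")]
        intra = [e for e in located if e.location == "intrachromosomal"]
        rep: dict = {
            "n_events": len(evs),
            "n_located": len(located),
            "n_intra": len(intra),
            "n_inter": len(located) - len(intra),
        }

        # cohort x location independence
        mat, rows, cols = cohort_statistics.cohort_contingency(located, "location")
        rep["location_by_cohort"] = {"rows": rows, "cols": cols,
                                     "table": mat.tolist(),
                                     "g_test": _try_g_independence(mat)}
        # orientation goodness of fit (direct vs inverse, equal expectation)
        n_dir = sum(1 for e in intra if e.orientation == "direct")
        n_inv = sum(1 for e in intra if e.orientation == "inverse")
        rep["orientation"] = {"direct": n_dir, "inverse": n_inv,
                              "g_test": _g(cohort_statistics.g_test_gof([n_dir, n_inv]))
                              if n_dir + n_inv else None}
        # orientation x cohort
        mat_o, rows_o, cols_o = cohort_statistics.cohort_contingency(intra, "orientation")
        rep["orientation_by_cohort"] = {"rows": rows_o, "cols": cols_o,
                                        "table": mat_o.tolist(),
                                        "g_test": _try_g_independence(mat_o)}
        # structural categories (DNA events) x cohort
        dna = [e for e in evs if e.mechanism == "DNA" and e.structural_class]
        mat_s, rows_s, cols_s = cohort_statistics.cohort_contingency(
            dna, "structural_class")
        rep["structure_by_cohort"] = {"rows": rows_s, "cols": cols_s,
                                      "table": mat_s.tolist(),
                                      "g_test": _try_g_independence(mat_s)}
        counts_by_class: dict[str, int] = {}
        for e in dna:
            counts_by_class[e.structural_class] = \
                counts_by_class.get(e.structural_class, 0) + 1
        rep["structure_counts"] = counts_by_class
        # mechanism x location
        mech_tab = np.zeros((2, 2))
        for e in located:
            i = 0 if e.mechanism == "DNA" else 1
            j = 0 if e.location == "intrachromosomal" else 1
            mech_tab[i, j] += 1
        rep["mechanism_by_location"] = {"rows": ["DNA", "RNA"],
                                        "cols": ["intra", "inter"],
                                        "table": mech_tab.tolist(),
                                        "g_test": _try_g_independence(mech_tab)}
        # chromosome frequencies
        if genes_per_chrom:
            for label, auto in (("chromosome_frequencies", False),
                                ("chromosome_frequencies_autosomes", True)):
                try:
                    cnt, freq, gt = cohort_statistics.chromosome_duplication_frequencies(
                        located, genes_per_chrom, autosomes_only=auto)
                    rep[label] = {"counts": cnt, "frequencies": freq, "g_test": _g(gt)}
                except ValueError:
                    rep[label] = None
        # centromere bins
        if centromeres:
            try:
                dup_b, gene_b, gt = cohort_statistics.centromere_distance_bins(
                    located, centromeres, gene_map)
                rep["centromere_bins"] = {"duplicates": dup_b.tolist(),
                                          "genes": gene_b.tolist(),
                                          "g_test": _g(gt)}
            except ValueError:
                rep["centromere_bins"] = None
        # trends
        tr = cohort_statistics.trend_and_rank_stats(evs, gene_map)
        rep["trends"] = {
            "kendall_span_ks_dna": tr.kendall_tau_span_ks_dna,
            "kendall_span_ks_rna": tr.kendall_tau_span_ks_rna,
            "pearson_ks_logdist": tr.pearson_r_ks_logdist,
            "wilcoxon_span_vs_gene_length": tr.wilcoxon_span_vs_gene_length,
            "wilcoxon_span_vs_coding_extent": tr.wilcoxon_span_vs_coding_extent,
        }
        report[name] = rep
    return report


def _try_g_independence(mat: np.ndarray) -> dict | None:
    try:
        return _g(cohort_statistics.g_test_independence(mat))
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# file-level entry points
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> Path:
    """Load inputs from the configured paths, analyze, write the output
    directory (events table, statistics report, logs, config echo)."""
    if not config.fasta or not config.gff3:
        raise PipelineError("fasta and gff3 inputs are required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("dupscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        genome, genes = annotation_io.load_genome_and_annotation(config.fasta,
                                                                 config.gff3)
        outgroup = None
        if config.outgroup_fasta and config.outgroup_gff3:
            outgroup = annotation_io.load_genome_and_annotation(
                config.outgroup_fasta, config.outgroup_gff3)
        centromeres = (read_centromere_table(config.centromere_table)
                       if config.centromere_table else None)
        result = analyze(genome, genes, config, outgroup=outgroup,
                         centromeres=centromeres)
    finally:
        root.removeHandler(handler)
        handler.close()

    write_events_table(result.events, out / "events.tsv")
    divergence_ks.write_pair_table(result.pairs_all, out / "pairs.tsv")
    gene_conversion.write_conversion_table(result.conversion, out / "conversion.tsv")
    with open(out / "statistics.json", "w") as fh:
        json.dump(_jsonable(result.statistics), fh, indent=2)
    with open(out / "counts.json", "w") as fh:
        json.dump(result.counts, fh, indent=2)
    with open(out / "config.yaml", "w") as fh:
        fh.write(config.to_yaml())
    with open(out / "trees.nwk", "w") as fh:
        for key in sorted(result.trees):
            fh.write(f"# {key}\n{result.trees[key]}\n")
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_events_table(events: list[DuplicationEvent], path) -> None:
    """One row per duplication event, mirroring the survey's event table."""
    cols = ["event_id", "gene1", "gene2", "n_member_pairs", "ks", "cohort",
            "chrom1", "chrom2", "location", "category", "orientation",
            "span", "distance", "mechanism", "conversion", "notes"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in events:
            row = [e.event_id, e.gene1, e.gene2, str(len(e.members)),
                   "" if e.ks is None else f"{e.ks:.6f}",
                   e.cohort or "", e.chrom1 or "", e.chrom2 or "",
                   e.location or "", e.category or "", e.orientation or "",
                   "" if e.span is None else str(int(e.span)),
                   "" if e.distance is None else str(int(e.distance)),
                   e.mechanism or "",
                   "" if e.conversion is None else str(e.conversion),
                   ";".join(e.notes)]
            fh.write("\t".join(row) + "\n")


def read_events_table(path) -> list[DuplicationEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            c = line.rstrip("\n").split("\t")

            def get(name, cast=str):
                v = c[idx[name]]
                return cast(v) if v else None

            ev = DuplicationEvent(
                event_id=c[idx["event_id"]], gene1=c[idx["gene1"]],
                gene2=c[idx["gene2"]], ks=get("ks", float),
                cohort=get("cohort"), chrom1=get("chrom1"), chrom2=get("chrom2"),
                location=get("location"), orientation=get("orientation"),
                span=get("span", lambda v: int(float(v))),
                distance=get("distance", lambda v: int(float(v))),
                mechanism=get("mechanism"))
            cat = get("category")
            if cat and cat != "retro":
                ev.structural_class = cat
            conv = get("conversion")
            ev.conversion = None if conv is None else conv == "True"
            ev.conversion_tested = conv is not None
            events.append(ev)
    return events


def read_centromere_table(path) -> dict[str, tuple[int, int]]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, s, e = line.split()[:3]
            out[chrom] = (int(s), int(e))
    return out
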