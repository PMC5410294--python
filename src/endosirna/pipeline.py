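"""End-to-end pipeline: preprocess -> map -> annotate -> classify ->
diffexpr -> l1scan -> report.

Each stage is a plain function over in-memory objects; ``run_pipeline``
wires them together from a flat key-value config, writes every stage's
TSV/BED/FASTA outputs under the output directory, and logs one line per
stage with record counts in and out. Two runs with the same config and
seed produce byte-identical output trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import pandas as pd

from . import annotate as ann_mod
from . import classify as cls_mod
from . import diffexpr as de_mod
from . import l1asp as l1_mod
from . import mapping as map_mod
from . import preprocess as pp_mod
from . import report as rep_mod
from .fold import HairpinStructure, fold_region
from .preprocess import SmallRNATag

log = logging.getLogger(__name__)

DEFAULT_CONFIG: Dict[str, object] = {
    "libraries": ["sperm", "oocyte", "zygote"],
    "adapter": "TGGAATTCTCGGGTGCCAAGG",
    "count_filter_scope": "total",
    "max_mismatches": 0,
    "cluster_max_span": 10000,
    "cluster_min_unique": 16,
    "cluster_scope": "any",  # 'any' mapped sncRNA or 'candidates' only
    "fold_max_region": 20000,
    "lhp_min_paired_fraction": 0.5,
    "lhp_min_arm": 20,
    "ic_match": 2.0,
    "ic_mismatch": -3.0,
    "ic_gap_open": -5.0,
    "ic_gap_ext": -2.0,
    "ic_min_length": 30,
    "ic_min_identity": 0.8,
    "homology_min_length": 50,
    "homology_min_identity": 0.8,
    "upstream_window": 3000,
    "asl1_span": [93, -490],
    "diff_focal": "zygote",
    "diff_comparators": ["sperm", "oocyte"],
    "fold_threshold": 2.0,
    "p_threshold": 0.01,
    "bh_correct": False,
    "seed": 0,
}

_PATH_KEYS = (
    "genome_fasta", "mirna_fasta", "pirna_fasta", "structural_fasta",
    "repeat_fasta", "mrna_fasta", "l1_bed", "l1_consensus_fasta",
)


@dataclass
class PipelineResult:
    config: Dict[str, object]
    tags: List[SmallRNATag] = field(default_factory=list)
    stats: Dict[str, pp_mod.FilterStats] = field(default_factory=dict)
    hits: Dict[str, map_mod.GenomeHit] = field(default_factory=dict)
    unmapped: List[str] = field(default_factory=list)
    annotations: Dict[str, ann_mod.AnnotationRecord] = field(default_factory=dict)
    te_calls: List[cls_mod.EndoSiRNACall] = field(default_factory=list)
    clusters: List[cls_mod.SiRNACluster] = field(default_factory=list)
    structures: Dict[str, HairpinStructure] = field(default_factory=dict)
    lhp_calls: List[cls_mod.EndoSiRNACall] = field(default_factory=list)
    ic_regions: List[cls_mod.ICRegion] = field(default_factory=list)
    ic_calls: List[cls_mod.EndoSiRNACall] = field(default_factory=list)
    final: Dict[str, cls_mod.FinalAnnotation] = field(default_factory=dict)
    selected: List[str] = field(default_factory=list)
    diff_results: List[de_mod.DiffResult] = field(default_factory=list)
    flanks: List[l1_mod.UpstreamFlank] = field(default_factory=list)
    blocks: List[l1_mod.HomologyBlock] = field(default_factory=list)
    duplex: Optional[l1_mod.DsRNADuplex] = None
    l1_assigned: List[Tuple[str, str]] = field(default_factory=list)
    summary: Optional[rep_mod.ClassSummary] = None

    @property
    def library_totals(self) -> Dict[str, int]:
        """Per-library read totals over mapped surviving tags."""
        libs = list(self.config["libraries"])
        mapped = [t for t in self.tags if t.tag_id in self.hits]
        return {l: sum(t.counts.get(l, 0) for t in mapped) for l in libs}

    def candidates(self) -> Set[str]:
        return {
            tid for tid, a in self.annotations.items()
            if a.label == "endo_siRNA_candidate"
        }


def validate_config(config: Mapping[str, object]) -> Dict[str, object]:
    """Merge with defaults and validate before any stage runs."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    for key in _PATH_KEYS + ("fastq_dir",):
        if key in cfg and cfg[key] is not None and not Path(str(cfg[key])).exists():
            raise FileNotFoundError(f"config {key}: no such path {cfg[key]!r}")
    if float(cfg["fold_threshold"]) <= 0:
        raise ValueError("fold_threshold must be positive")
    if not 0 < float(cfg["p_threshold"]) <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    if not 0 < float(cfg["lhp_min_paired_fraction"]) <= 1:
        raise ValueError("lhp_min_paired_fraction must be in (0, 1]")
    if int(cfg["cluster_min_unique"]) < 1 or int(cfg["cluster_max_span"]) < 1:
        raise ValueError("cluster thresholds must be positive")
    if not 0 <= float(cfg["ic_min_identity"]) <= 1:
        raise ValueError("ic_min_identity must be in [0, 1]")
    return cfg


# -------------------------------------------------------------- stages

def stage_preprocess(cfg, fastq_paths: Mapping[str, str | Path]):
    tags, stats = pp_mod.collapse_fastq_files(
        fastq_paths, str(cfg["adapter"]), str(cfg["count_filter_scope"])
    )
    n_in = sum(s.input_reads for s in stats.values())
    log.info("stage preprocess: %d reads in, %d tags out", n_in, len(tags))
    return tags, stats


def stage_map(cfg, tags, genome: Mapping[str, str]):
    index = map_mod.build_index(genome)
    hits, unmapped = map_mod.map_tags(tags, index)
    log.info("stage map: %d tags in, %d mapped, %d unmapped discarded",
             len(tags), len(hits), len(unmapped))
    return hits, unmapped


def stage_annotate(cfg, tags, hits, refs):
    mapped_tags = [t for t in tags if t.tag_id in hits]
    annotations = ann_mod.annotate_tiers(mapped_tags, refs, int(cfg["max_mismatches"]))
    counts = pd.Series([a.label for a in annotations.values()]).value_counts()
    log.info("stage annotate: %d tags in, labels %s", len(mapped_tags),
             counts.to_dict())
    return annotations


def stage_classify(cfg, tags, hits, annotations, repeat_records, mrnas,
                   genome: Mapping[str, str]):
    """TE / Lhp / IC calls and final labels."""
    by_id = {t.tag_id: t for t in tags}
    cand_ids = {
        tid for tid, a in annotations.items() if a.label == "endo_siRNA_candidate"
    }
    candidates = [by_id[tid] for tid in sorted(cand_ids)]

    te_calls = cls_mod.classify_te(candidates, repeat_records)

    if str(cfg["cluster_scope"]) == "candidates":
        cluster_hits = [hits[tid] for tid in sorted(cand_ids) if tid in hits]
    else:
        cluster_hits = [hits[tid] for tid in sorted(hits)]
    sequences = {t.tag_id: t.sequence for t in tags}
    clusters = cls_mod.find_clusters(
        cluster_hits, sequences,
        int(cfg["cluster_max_span"]), int(cfg["cluster_min_unique"]),
    )
    structures: Dict[str, HairpinStructure] = {}
    lhp_calls: List[cls_mod.EndoSiRNACall] = []
    for cluster in clusters:
        region = genome[cluster.chrom][cluster.start : cluster.end]
        if not 40 <= len(region) <= int(cfg["fold_max_region"]):
            log.warning("cluster %s region %d nt outside foldable range; skipped",
                        cluster.cluster_id, len(region))
            continue
        structure = fold_region(region)
        structures[cluster.cluster_id] = structure
        lhp_calls.extend(
            cls_mod.classify_lhp(
                cluster, structure, hits, cand_ids,
                float(cfg["lhp_min_paired_fraction"]), int(cfg["lhp_min_arm"]),
            )
        )

    ic_regions: List[cls_mod.ICRegion] = []
    ic_calls: List[cls_mod.EndoSiRNACall] = []
    if mrnas:
        for mrna_id in sorted(mrnas):
            ic_regions.extend(
                cls_mod.find_inverted_complement(
                    mrna_id, mrnas[mrna_id],
                    float(cfg["ic_match"]), float(cfg["ic_mismatch"]),
                    float(cfg["ic_gap_open"]), float(cfg["ic_gap_ext"]),
                    int(cfg["ic_min_length"]), float(cfg["ic_min_identity"]),
                )
            )
        mrna_index = map_mod.build_index(mrnas)
        mrna_hits, _ = map_mod.map_tags(candidates, mrna_index)
        ic_calls = cls_mod.assign_ic(mrna_hits, ic_regions, cand_ids)

    final = cls_mod.finalize_labels(annotations, te_calls + lhp_calls + ic_calls)
    log.info(
        "stage classify: %d candidates -> %d TE, %d Lhp, %d IC calls; "
        "%d clusters, %d IC regions",
        len(candidates), len(te_calls), len(lhp_calls), len(ic_calls),
        len(clusters), len(ic_regions),
    )
    return te_calls, clusters, structures, lhp_calls, ic_regions, ic_calls, final


def stage_diffexpr(cfg, tags, final, totals):
    endo_ids = {tid for tid, f in final.items() if f.label == "endo_siRNA"}
    endo_tags = [t for t in tags if t.tag_id in endo_ids]
    focal = str(cfg["diff_focal"])
    comparators = [str(c) for c in cfg["diff_comparators"]]
    selected, results = de_mod.select_enriched(
        endo_tags, totals, focal, comparators,
        float(cfg["fold_threshold"]), float(cfg["p_threshold"]),
        bool(cfg["bh_correct"]),
    )
    log.info("stage diffexpr: %d endo-siRNAs in, %d selected", len(endo_tags),
             len(selected))
    return selected, results


def stage_l1scan(cfg, tags, final, genome, l1_bed, l1_consensus: str,
                 l1_target: Tuple[int, int]):
    """asL1 homology scan, duplex construction and L1-siRNA assignment."""
    flanks = l1_mod.extract_upstream(genome, l1_bed, int(cfg["upstream_window"]))
    t_lo, t_hi = l1_target
    blocks = l1_mod.find_homology(
        flanks, l1_consensus[t_lo:t_hi], target_offset=t_lo,
        min_length=int(cfg["homology_min_length"]),
        min_identity=float(cfg["homology_min_identity"]),
    )
    span = tuple(int(v) for v in cfg["asl1_span"])
    duplex = None
    for block in blocks:
        d = l1_mod.build_duplex(span, block)
        if duplex is None or (d.length, d.block.score) > (
            duplex.length, duplex.block.score
        ):
            duplex = d
    assigned: List[Tuple[str, str]] = []
    if duplex is not None and duplex.active:
        cand_ids = {
            tid for tid, f in final.items()
            if f.label == "endo_siRNA" or f.label == "unknown"
        }
        by_id = {t.tag_id: t for t in tags}
        cands = [by_id[tid] for tid in sorted(cand_ids) if tid in by_id]
        index = map_mod.build_index({"L1": l1_consensus})
        transcript_hits, _ = map_mod.map_tags(cands, index)
        assigned = l1_mod.assign_l1_sirnas(transcript_hits, duplex)
    log.info("stage l1scan: %d flanks, %d blocks, duplex %s nt, %d tags assigned",
             len(flanks), len(blocks),
             duplex.length if duplex else "-", len(assigned))
    return flanks, blocks, duplex, assigned


def stage_report(cfg, tags, final):
    libs = [str(l) for l in cfg["libraries"]]
    mapped = [t for t in tags if t.tag_id in {f for f in final}]
    summary = rep_mod.summarize(final, mapped, libs)
    log.info("stage report: totals %s",
             {l: summary.total_sequences(l) for l in libs})
    return summary


# ------------------------------------------------------------ full run

STAGES = ("preprocess", "map", "annotate", "classify", "diffexpr", "l1scan",
          "report")


def run_pipeline(config: Mapping[str, object],
                 outdir: str | Path | None = None,
                 stop_after: Optional[str] = None) -> PipelineResult:
    """Run every stage from a flat config; write outputs if ``outdir``.

    Required config keys: ``fastq_dir`` (containing ``<library>.fastq``)
    and ``genome_fasta``; the reference/repeat/mRNA/L1 inputs are optional
    and their stages degrade gracefully when absent. ``stop_after`` halts
    the run after the named stage.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    cfg = validate_config(config)

    def _done(stage: str) -> bool:
        return stop_after == stage
    libs = [str(l) for l in cfg["libraries"]]
    fastq_dir = Path(str(cfg["fastq_dir"]))
    fastq_paths = {}
    for lib in libs:
        p = fastq_dir / f"{lib}.fastq"
        if not p.exists():
            raise FileNotFoundError(f"missing library FASTQ {p}")
        fastq_paths[lib] = p
    genome = map_mod.read_fasta(str(cfg["genome_fasta"]))

    refs: Dict[str, ann_mod.ReferenceSet] = {}
    for kind, key in (
        ("miRNA", "mirna_fasta"),
        ("piRNA", "pirna_fasta"),
        ("structural_ncRNA", "structural_fasta"),
    ):
        if cfg.get(key):
            refs[kind] = ann_mod.ReferenceSet.from_fasta(kind, str(cfg[key]))
    repeat_records = (
        cls_mod.read_repeat_library(str(cfg["repeat_fasta"]))
        if cfg.get("repeat_fasta") else []
    )
    mrnas = map_mod.read_fasta(str(cfg["mrna_fasta"])) if cfg.get("mrna_fasta") else {}

    result = PipelineResult(config=cfg)

    def _finish():
        if outdir is not None:
            write_outputs(result, Path(outdir))
        return result

    result.tags, result.stats = stage_preprocess(cfg, fastq_paths)
    if _done("preprocess"):
        return _finish()
    result.hits, result.unmapped = stage_map(cfg, result.tags, genome)
    if _done("map"):
        return _finish()
    result.annotations = stage_annotate(cfg, result.tags, result.hits, refs)
    if _done("annotate"):
        return _finish()
    (
        result.te_calls, result.clusters, result.structures, result.lhp_calls,
        result.ic_regions, result.ic_calls, result.final,
    ) = stage_classify(cfg, result.tags, result.hits, result.annotations,
                       repeat_records, mrnas, genome)
    if _done("classify"):
        return _finish()
    totals = result.library_totals
    comparators = list(cfg["diff_comparators"])
    if comparators and all(
        totals.get(str(l), 0) > 0 for l in [cfg["diff_focal"], *comparators]
    ):
        result.selected, result.diff_results = stage_diffexpr(
            cfg, result.tags, result.final, totals
        )
    if _done("diffexpr"):
        return _finish()
    if cfg.get("l1_bed") and cfg.get("l1_consensus_fasta"):
        consensus = map_mod.read_fasta(str(cfg["l1_consensus_fasta"]))
        l1_seq = next(iter(consensus.values()))
        target = (
            int(cfg.get("l1_target_start", 0)),
            int(cfg.get("l1_target_end", len(l1_seq))),
        )
        (
            result.flanks, result.blocks, result.duplex, result.l1_assigned,
        ) = stage_l1scan(cfg, result.tags, result.final, genome,
                         str(cfg["l1_bed"]), l1_seq, target)
    if _done("l1scan"):
        return _finish()
    result.summary = stage_report(cfg, result.tags, result.final)
    return _finish()


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    libs = [str(l) for l in cfg["libraries"]]
    pp_mod.write_tags_tsv(result.tags, libs, outdir / "tags.tsv")
    pp_mod.write_tags_fasta(result.tags, outdir / "tags.fasta")
    scores = {t.tag_id: t.total_count for t in result.tags}
    map_mod.write_hits_bed(result.hits, scores, outdir / "hits.bed")
    (outdir / "unmapped.txt").write_text(
        "".join(f"{tid}\n" for tid in sorted(result.unmapped))
    )
    ann_mod.write_annotations_tsv(result.annotations, outdir / "annotations.tsv")
    with open(outdir / "subclass_calls.tsv", "w") as fh:
        fh.write("tag_id\tsubclass\tfamily\tlocus\n")
        for c in sorted(
            result.te_calls + result.lhp_calls + result.ic_calls,
            key=lambda c: (c.tag_id, c.subclass),
        ):
            fh.write(f"{c.tag_id}\t{c.subclass}\t{c.family}\t{c.locus}\n")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tchrom\tstart\tend\tspan\tdistinct_sequences\t"
                 "paired_fraction\tarm5\tarm3\n")
        for cl in result.clusters:
            s = result.structures.get(cl.cluster_id)
            pf = f"{s.paired_fraction:.4f}" if s else ""
            a5 = f"{s.arm5[0]}-{s.arm5[1]}" if s and s.arm5 else ""
            a3 = f"{s.arm3[0]}-{s.arm3[1]}" if s and s.arm3 else ""
            fh.write(f"{cl.cluster_id}\t{cl.chrom}\t{cl.start}\t{cl.end}\t"
                     f"{cl.span}\t{cl.distinct_sequences}\t{pf}\t{a5}\t{a3}\n")
    with open(outdir / "ic_regions.bed", "w") as fh:  # mRNA-space BED
        for r in result.ic_regions:
            fh.write(f"{r.mrna_id}\t{r.arm1[0]}\t{r.arm1[1]}\t"
                     f"ic_arm1;identity={r.identity:.3f}\t0\t+\n")
            fh.write(f"{r.mrna_id}\t{r.arm2[0]}\t{r.arm2[1]}\t"
                     f"ic_arm2;identity={r.identity:.3f}\t0\t-\n")
    cls_mod.write_final_tsv(result.final, outdir / "final_annotations.tsv")
    de_mod.write_diff_tsv(result.diff_results, outdir / "diff_results.tsv")
    (outdir / "selected_tags.tsv").write_text(
        "tag_id\n" + "".join(f"{tid}\n" for tid in result.selected)
    )
    with open(outdir / "l1_upstream.fasta", "w") as fh:
        for f in result.flanks:
            trunc = " truncated" if f.truncated else ""
            fh.write(f">{f.l1_id} {f.chrom}:{f.start}-{f.end}({f.strand}){trunc}\n"
                     f"{f.sequence}\n")
    with open(outdir / "homology_blocks.tsv", "w") as fh:
        fh.write("l1_id\tupstream_from\tupstream_to\ttarget_start\ttarget_end\t"
                 "length\tidentity\tscore\n")
        for blk in result.blocks:
            fh.write(f"{blk.l1_id}\t{blk.upstream_from}\t{blk.upstream_to}\t"
                     f"{blk.target_start}\t{blk.target_end}\t{blk.length}\t"
                     f"{blk.identity:.4f}\t{blk.score:.1f}\n")
    with open(outdir / "duplex.tsv", "w") as fh:
        fh.write("asl1_span\tduplex_length\tsense_interval\tactive\tn_assigned\n")
        d = result.duplex
        if d is not None:
            span = f"{d.asl1_span[0]:+d}..{d.asl1_span[1]:+d}"
            sense = f"{d.sense_interval[0]}-{d.sense_interval[1]}" if d.sense_interval else ""
            fh.write(f"{span}\t{d.length}\t{sense}\t{int(d.active)}\t"
                     f"{len(d.assigned)}\n")
    with open(outdir / "l1_assignments.tsv", "w") as fh:
        fh.write("tag_id\tstrand\n")
        for tid, strand in result.l1_assigned:
            fh.write(f"{tid}\t{strand}\n")
    if result.summary is not None:
        rep_mod.write_summary(result.summary, outdir / "summary.tsv",
                              outdir / "summary.md")
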