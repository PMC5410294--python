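"""Subclassification of endo-siRNA candidates: TE-, Lhp- and IC-siRNAs.

Three structural rules, mirroring how endo-siRNA precursors arise:

* TE-siRNA — the tag perfectly matches (either strand) a repeat-library
  record tagged with one of the families LTR / SINE / L1 / ERV;
* Lhp-siRNA — the tag maps inside an arm of a long hairpin folded from a
  genomic cluster region (> 15 unique small-RNA sequences within < 10 kb);
* IC-siRNA — the tag maps inside an arm of an inverted-complement region
  of an mRNA.

Candidates matching none of the rules revert to "unknown". When several
rules fire for one tag, priority is TE > Lhp > IC (a repeat match is the
most specific sequence-level evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from Bio import SeqIO

from ._seq import revcomp
from .align import local_align_all
from .annotate import AnnotationRecord
from .fold import HairpinStructure
from .mapping import GenomeHit

log = logging.getLogger(__name__)

TE_FAMILIES = ("LTR", "SINE", "L1", "ERV")
CLUSTER_MAX_SPAN = 10000  # strict: span must be < 10 kb
CLUSTER_MIN_UNIQUE = 16  # "more than 15" unique sequences
LHP_MIN_PAIRED_FRACTION = 0.5
LHP_MIN_ARM = 20
IC_MIN_LENGTH = 30
IC_MIN_IDENTITY = 0.8
SUBCLASS_PRIORITY = ("TE", "Lhp", "IC")


@dataclass(frozen=True)
class EndoSiRNACall:
    tag_id: str
    subclass: str  # 'TE' | 'Lhp' | 'IC'
    family: str = ""  # TE family, empty otherwise
    locus: str = ""

    def __post_init__(self):
        if self.subclass not in SUBCLASS_PRIORITY:
            raise ValueError(f"bad subclass {self.subclass!r}")
        if (self.subclass == "TE") != bool(self.family):
            raise ValueError("family must be set iff subclass is TE")
        if not self.locus:
            raise ValueError("locus must be set")


@dataclass
class SiRNACluster:
    chrom: str
    start: int
    end: int
    member_tag_ids: List[str]
    distinct_sequences: int
    cluster_id: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ICRegion:
    mrna_id: str
    arm1: Tuple[int, int]  # half-open, on the mRNA
    arm2: Tuple[int, int]
    region_length: int
    identity: float
    score: float


# ---------------------------------------------------------------- TE rule

def read_repeat_library(path: str | Path) -> List[Tuple[str, str, str]]:
    """Parse a repeat library FASTA whose headers carry ``family=`` tags.

    Returns (record_id, family, sequence) in file order; a record without
    a parsable family tag is rejected by name.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        family = None
        for token in rec.description.split():
            if token.startswith("family="):
                family = token.split("=", 1)[1]
        if not family:
            raise ValueError(f"repeat record {rec.id!r} lacks a family= tag")
        out.append((rec.id, family, str(rec.seq).upper()))
    return out


def classify_te(
    candidates: Iterable,
    repeat_records: Sequence[Tuple[str, str, str]],
) -> List[EndoSiRNACall]:
    """TE calls for candidates perfectly matching a repeat record.

    ``candidates`` yields objects with ``tag_id`` and ``sequence``. Ties
    across records (and families) are broken by record order in the
    library file; multi-family matches are logged.
    """
    calls = []
    for tag in candidates:
        seq = tag.sequence
        matched = []
        for rec_id, family, rec_seq in repeat_records:
            if seq in rec_seq or seq in revcomp(rec_seq):
                matched.append((rec_id, family))
        if not matched:
            continue
        rec_id, family = matched[0]
        families = {f for _, f in matched}
        if len(families) > 1:
            log.info(
                "tag %s matches families %s; keeping first record %s (%s)",
                tag.tag_id, sorted(families), rec_id, family,
            )
        calls.append(EndoSiRNACall(tag.tag_id, "TE", family, rec_id))
    return calls


# ------------------------------------------------------------ Lhp rule

def find_clusters(
    hits: Iterable[GenomeHit],
    sequences: Mapping[str, str],
    max_span: int = CLUSTER_MAX_SPAN,
    min_unique: int = CLUSTER_MIN_UNIQUE,
) -> List[SiRNACluster]:
    """Greedy left-to-right clustering of mapped small-RNA hits.

    Hits are sorted per chromosome; the current run is extended while the
    span from the first hit's start to the candidate hit's end stays
    strictly below ``max_span``. A run is emitted iff it contains at least
    ``min_unique`` distinct tag sequences.
    """
    by_chrom: Dict[str, List[GenomeHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    clusters: List[SiRNACluster] = []
    for chrom in sorted(by_chrom):
        chrom_hits = sorted(by_chrom[chrom], key=lambda h: (h.start, h.end, h.tag_id))
        run: List[GenomeHit] = []
        for h in chrom_hits + [None]:  # sentinel flushes the last run
            if h is not None and (not run or h.end - run[0].start < max_span):
                run.append(h)
                continue
            if run:
                distinct = len({sequences[x.tag_id] for x in run})
                if distinct >= min_unique:
                    start = run[0].start
                    end = max(x.end for x in run)
                    clusters.append(
                        SiRNACluster(
                            chrom, start, end, [x.tag_id for x in run], distinct,
                            cluster_id=f"cluster_{chrom}_{start}",
                        )
                    )
            run = [h] if h is not None else []
    return clusters


def classify_lhp(
    cluster: SiRNACluster,
    structure: HairpinStructure,
    hits: Mapping[str, GenomeHit],
    candidates: Set[str],
    min_paired_fraction: float = LHP_MIN_PAIRED_FRACTION,
    min_arm: int = LHP_MIN_ARM,
) -> List[EndoSiRNACall]:
    """Lhp calls for candidate tags lying entirely within a hairpin arm.

    The cluster region qualifies as a long hairpin iff its paired fraction
    is >= ``min_paired_fraction`` and both arms are >= ``min_arm`` nt.
    """
    a5, a3 = structure.arm_lengths()
    if structure.paired_fraction < min_paired_fraction or min(a5, a3) < min_arm:
        return []
    calls = []
    for tid in cluster.member_tag_ids:
        if tid not in candidates:
            continue
        h = hits[tid]
        rel = (h.start - cluster.start, h.end - cluster.start)
        for arm in (structure.arm5, structure.arm3):
            if arm and arm[0] <= rel[0] and rel[1] <= arm[1]:
                calls.append(EndoSiRNACall(tid, "Lhp", "", cluster.cluster_id))
                break
    return calls


# ------------------------------------------------------------- IC rule

def find_inverted_complement(
    mrna_id: str,
    mrna_seq: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_ext: float = -2.0,
    min_length: int = IC_MIN_LENGTH,
    min_identity: float = IC_MIN_IDENTITY,
) -> List[ICRegion]:
    """Inverted-complement regions of one mRNA.

    The mRNA is locally aligned against its own reverse complement under a
    half-matrix restriction (see :mod:`endosirna.align`), which discards
    self-overlapping arm projections by construction and keeps one of each
    mirror-duplicate pair. Alignments with aligned length >= ``min_length``
    and identity >= ``min_identity`` become ICRegions; overlapping regions
    are merged keeping the higher-scoring one.
    """
    L = len(mrna_seq)
    if L < 60:
        raise ValueError(f"mRNA {mrna_id!r} shorter than 60 nt")
    alns = local_align_all(
        mrna_seq, revcomp(mrna_seq), match, mismatch, gap_open, gap_ext,
        min_length=min_length, min_identity=min_identity, half_matrix=True,
    )
    regions: List[ICRegion] = []
    for a in alns:
        arm1 = (a.t_start, a.t_end)
        arm2 = (L - a.q_end, L - a.q_start)
        if arm1[1] - arm1[0] != arm2[1] - arm2[0]:
            continue  # unbalanced gaps: arms of unequal length are not IRs
        if arm1[1] > arm2[0]:
            continue  # overlapping projections (defensive; half-matrix bars it)
        regions.append(
            ICRegion(mrna_id, arm1, arm2, arm1[1] - arm1[0], a.identity, a.score)
        )
    regions.sort(key=lambda r: -r.score)
    kept: List[ICRegion] = []
    for r in regions:
        if any(_ic_overlap(r, k) for k in kept):
            continue
        kept.append(r)
    kept.sort(key=lambda r: r.arm1)
    return kept


def _ic_overlap(a: ICRegion, b: ICRegion) -> bool:
    def ov(x, y):
        return x[0] < y[1] and y[0] < x[1]

    return any(ov(x, y) for x in (a.arm1, a.arm2) for y in (b.arm1, b.arm2))


def assign_ic(
    mrna_hits: Mapping[str, GenomeHit],
    regions: Sequence[ICRegion],
    candidates: Set[str],
) -> List[EndoSiRNACall]:
    """IC calls for candidate tags whose mRNA hit lies entirely within an
    arm of an ICRegion (strict containment; the mRNA id is the locus)."""
    calls = []
    for tid in sorted(mrna_hits):
        if tid not in candidates:
            continue
        h = mrna_hits[tid]
        for r in regions:
            if h.chrom != r.mrna_id:
                continue
            for arm in (r.arm1, r.arm2):
                if arm[0] <= h.start and h.end <= arm[1]:
                    calls.append(EndoSiRNACall(tid, "IC", "", r.mrna_id))
                    break
            else:
                continue
            break
    return calls


# ----------------------------------------------------------- finalize

FINAL_LABELS = ("miRNA", "piRNA", "structural_ncRNA", "endo_siRNA", "unknown")


@dataclass(frozen=True)
class FinalAnnotation:
    tag_id: str
    label: str
    subclass: str = ""  # TE | Lhp | IC for endo_siRNA
    family: str = ""
    locus: str = ""
    evidence: str = ""


def finalize_labels(
    annotations: Mapping[str, AnnotationRecord],
    calls: Iterable[EndoSiRNACall],
) -> Dict[str, FinalAnnotation]:
    """Reconcile tier annotations with subclass calls.

    Candidates with at least one call become endo-siRNAs (priority
    TE > Lhp > IC, multi-calls logged); candidates without a call revert
    to "unknown"; non-candidate tiers pass through unchanged.
    """
    by_tag: Dict[str, List[EndoSiRNACall]] = {}
    for c in calls:
        by_tag.setdefault(c.tag_id, []).append(c)
    out: Dict[str, FinalAnnotation] = {}
    for tid, ann in annotations.items():
        if ann.label != "endo_siRNA_candidate":
            out[tid] = FinalAnnotation(tid, ann.label, evidence=ann.evidence)
            continue
        tag_calls = by_tag.get(tid, [])
        if not tag_calls:
            out[tid] = FinalAnnotation(tid, "unknown")
            continue
        if len({c.subclass for c in tag_calls}) > 1:
            log.info(
                "tag %s has multiple subclass calls %s; priority TE > Lhp > IC",
                tid, sorted({c.subclass for c in tag_calls}),
            )
        best = min(tag_calls, key=lambda c: SUBCLASS_PRIORITY.index(c.subclass))
        out[tid] = FinalAnnotation(
            tid, "endo_siRNA", best.subclass, best.family, best.locus
        )
    return out


def write_final_tsv(final: Mapping[str, FinalAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\tlabel\tsubclass\tfamily\tlocus\tevidence\n")
        for tid in sorted(final):
            f = final[tid]
            fh.write(
                f"{f.tag_id}\t{f.label}\t{f.subclass}\t{f.family}\t"
                f"{f.locus}\t{f.evidence}\n"
            )
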