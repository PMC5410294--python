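"""LINE-1 antisense-promoter (ASP) dsRNA modeling.

The L1 5'UTR can drive antisense transcription into the upstream flank.
Where that flank carries a block homologous (in antisense orientation) to
the L1 ORF2 / 3'UTR, the resulting antisense noncoding transcript (asL1)
can anneal with the L1 transcript into a double-stranded region — the
DICER substrate that yields L1-specific siRNAs. This module extracts
upstream flanks of annotated L1 copies, finds antisense homology blocks,
intersects a block with the asL1 transcript span to get the dsRNA duplex,
and assigns small-RNA tags to it.

Promoter coordinates: +1 is the first transcribed base at the L1 TSS, -1
the first base upstream of it; there is no position 0. Internally a
coordinate c maps to the integer line as ``c - 1`` for c > 0 and ``c``
for c < 0, making interval arithmetic ordinary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Set, Tuple

from ._seq import revcomp
from .align import local_align_all
from .mapping import GenomeHit

HOMOLOGY_MIN_LENGTH = 50
HOMOLOGY_MIN_IDENTITY = 0.8
UPSTREAM_WINDOW = 3000


# ------------------------------------------------- promoter coordinates

def check_coord(coord: int) -> int:
    if coord == 0:
        raise ValueError("promoter coordinate 0 does not exist")
    return int(coord)


def coord_to_line(coord: int) -> int:
    """Map a no-zero promoter coordinate onto the integer line (+1 -> 0)."""
    check_coord(coord)
    return coord - 1 if coord > 0 else coord


def line_to_coord(line: int) -> int:
    return line + 1 if line >= 0 else line


def promoter_to_offset(coord: int, tss: int, strand: str) -> int:
    """Genomic 0-based offset of a promoter coordinate.

    ``tss`` is the genomic offset of the +1 base; ``strand`` is the
    transcription direction of the L1 element.
    """
    line = coord_to_line(coord)
    return tss + line if strand == "+" else tss - line


def offset_to_promoter(offset: int, tss: int, strand: str) -> int:
    line = offset - tss if strand == "+" else tss - offset
    return line_to_coord(line)


def span_line_interval(span: Tuple[int, int]) -> Tuple[int, int]:
    """Inclusive integer-line interval covered by a promoter-coord pair."""
    a, b = (coord_to_line(c) for c in span)
    return (min(a, b), max(a, b))


def span_length(span: Tuple[int, int]) -> int:
    lo, hi = span_line_interval(span)
    return hi - lo + 1


# ------------------------------------------------------- upstream flanks

@dataclass
class UpstreamFlank:
    l1_id: str
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str
    sequence: str  # oriented 5'->3' in the element's transcription direction
    truncated: bool = False

    @property
    def window(self) -> int:
        return len(self.sequence)


def parse_bed6(path_or_rows) -> List[Tuple[str, int, int, str, int, str]]:
    """Parse 6-column BED; malformed lines are rejected with line numbers."""
    if isinstance(path_or_rows, (str, Path)):
        with open(path_or_rows) as fh:
            lines = fh.read().splitlines()
    else:
        return list(path_or_rows)
    rows = []
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"BED line {i}: expected 6 columns, got {len(parts)}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"BED line {i}: non-integer coordinates") from exc
        if parts[5] not in "+-":
            raise ValueError(f"BED line {i}: bad strand {parts[5]!r}")
        if not 0 <= start < end:
            raise ValueError(f"BED line {i}: bad interval {start}..{end}")
        rows.append((parts[0], start, end, parts[3], int(float(parts[4])), parts[5]))
    return rows


def extract_upstream(
    genome: Mapping[str, str],
    l1_bed,
    window: int = UPSTREAM_WINDOW,
) -> List[UpstreamFlank]:
    """Upstream flank (default 3000 nt) of every annotated L1 copy.

    For '+' copies this is the ``window`` nt 5' of the element start; for
    '-' copies, the reverse complement of the ``window`` nt 3' of the
    element end. Flanks clipped by a chromosome end are truncated and
    flagged.
    """
    flanks = []
    for chrom, start, end, name, _score, strand in parse_bed6(l1_bed):
        if chrom not in genome:
            raise ValueError(f"L1 annotation on unknown chromosome {chrom!r}")
        chrom_len = len(genome[chrom])
        if strand == "+":
            lo, hi = max(0, start - window), start
            seq = genome[chrom][lo:hi]
            truncated = start - window < 0
        else:
            lo, hi = end, min(chrom_len, end + window)
            seq = revcomp(genome[chrom][lo:hi])
            truncated = end + window > chrom_len
        flanks.append(UpstreamFlank(name, chrom, lo, hi, strand, seq, truncated))
    return flanks


# ------------------------------------------------------ homology blocks

@dataclass(frozen=True)
class HomologyBlock:
    """Antisense homology between an L1 upstream flank and a transcript
    target region (ORF2 and/or 3'UTR).

    ``upstream_from`` is the TSS-proximal end (e.g. -1), ``upstream_to``
    the distal end (e.g. -365), both promoter coordinates. The target
    interval is half-open in transcript offsets.
    """

    l1_id: str
    upstream_from: int
    upstream_to: int
    target_start: int
    target_end: int
    score: float
    identity: float
    length: int
    orientation: str = "antisense"


def find_homology(
    flanks: Sequence[UpstreamFlank],
    target_seq: str,
    target_offset: int = 0,
    min_length: int = HOMOLOGY_MIN_LENGTH,
    min_identity: float = HOMOLOGY_MIN_IDENTITY,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_ext: float = -2.0,
) -> List[HomologyBlock]:
    """Local antisense alignments of upstream flanks against a target.

    Each flank is aligned against the reverse complement of
    ``target_seq`` (length >= 100 nt); blocks with aligned length >=
    ``min_length`` and identity >= ``min_identity`` are reported, with
    upstream intervals converted to promoter coordinates and target
    intervals shifted by ``target_offset`` (the target's transcript
    offset).
    """
    if len(target_seq) < 100:
        raise ValueError("target region must be at least 100 nt")
    rc_target = revcomp(target_seq)
    lt = len(target_seq)
    blocks: List[HomologyBlock] = []
    for flank in flanks:
        if flank.window < min_length:
            continue
        w = flank.window
        for a in local_align_all(
            flank.sequence, rc_target, match, mismatch, gap_open, gap_ext,
            min_length=min_length, min_identity=min_identity,
        ):
            blocks.append(
                HomologyBlock(
                    l1_id=flank.l1_id,
                    upstream_from=line_to_coord(a.t_end - 1 - w),
                    upstream_to=line_to_coord(a.t_start - w),
                    target_start=target_offset + lt - a.q_end,
                    target_end=target_offset + lt - a.q_start,
                    score=a.score,
                    identity=round(a.identity, 6),
                    length=a.columns,
                )
            )
    blocks.sort(key=lambda b: (-b.score, b.l1_id))
    return blocks


# -------------------------------------------------------------- duplex

@dataclass
class DsRNADuplex:
    asl1_span: Tuple[int, int]  # promoter coords, e.g. (+93, -490)
    block: Optional[HomologyBlock]
    length: int
    sense_interval: Optional[Tuple[int, int]]  # transcript offsets, half-open
    active: bool
    assigned: List[Tuple[str, str]] = field(default_factory=list)


def build_duplex(
    asl1_span: Tuple[int, int], block: HomologyBlock
) -> DsRNADuplex:
    """Intersect a homology block with the asL1 span.

    The duplex length is the number of integer-line positions shared by
    the block's upstream interval and the asL1 span; an empty intersection
    yields a zero-length duplex flagged inactive. The sense-side interval
    is the block's target sub-interval matched by the intersection
    (antisense colinearity: the TSS-proximal upstream end pairs with the
    target interval start).
    """
    span_lo, span_hi = span_line_interval(asl1_span)
    blk_lo = coord_to_line(block.upstream_to)
    blk_hi = coord_to_line(block.upstream_from)
    if blk_lo > blk_hi:
        blk_lo, blk_hi = blk_hi, blk_lo
    lo = max(span_lo, blk_lo)
    hi = min(span_hi, blk_hi)
    if hi < lo:
        return DsRNADuplex(asl1_span, block, 0, None, active=False)
    length = hi - lo + 1
    sense = (
        block.target_start + (blk_hi - hi),
        block.target_start + (blk_hi - lo) + 1,
    )
    return DsRNADuplex(asl1_span, block, length, sense, active=True)


def assign_l1_sirnas(
    transcript_hits: Mapping[str, GenomeHit],
    duplex: DsRNADuplex,
    candidates: Optional[Set[str]] = None,
) -> List[Tuple[str, str]]:
    """Tags whose L1-transcript hit lies entirely within the duplex's
    sense-side interval, labeled sense/antisense by hit strand.

    Mutates ``duplex.assigned`` and returns the assignment list.
    """
    assigned: List[Tuple[str, str]] = []
    if duplex.active and duplex.sense_interval is not None:
        lo, hi = duplex.sense_interval
        for tid in sorted(transcript_hits):
            if candidates is not None and tid not in candidates:
                continue
            h = transcript_hits[tid]
            if lo <= h.start and h.end <= hi:
                assigned.append((tid, "sense" if h.strand == "+" else "antisense"))
    duplex.assigned = assigned
    return assigned


# ------------------------------------------------------ assay arithmetic

def spliced_product_length(product_with_intron: int, intron: int) -> int:
    """PCR product length after intron splicing (reporter arithmetic)."""
    if not 0 <= intron < product_with_intron:
        raise ValueError("need 0 <= intron < product_with_intron")
    return product_with_intron - intron


def fold_change_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)
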