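"""Tiered annotation of mapped tags: structural ncRNA, miRNA, piRNA,
endo-siRNA candidate, unknown.

Tier order (first match wins):

1. structural ncRNA — homologous to any tRNA/rRNA/snRNA/snoRNA reference;
2. miRNA — length 21-24 nt and homologous to a miRNA reference;
3. piRNA — homologous to a piRNA reference OR length 25-30 nt;
4. endo-siRNA candidate — length 18-24 nt;
5. unknown — defensive catch-all (tiers 3-4 cover 18-30 nt).

"Homologous" is operationalized as an exact substring match of the tag in
a reference sequence or its reverse complement (a perfect-match criterion);
the tolerance is a config knob that defaults to 0 mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO

from ._seq import revcomp

log = logging.getLogger(__name__)

LABELS = ("structural_ncRNA", "miRNA", "piRNA", "endo_siRNA_candidate", "unknown")
MIRNA_MIN, MIRNA_MAX = 21, 24
CAND_MIN, CAND_MAX = 18, 24
PIRNA_LEN_MIN, PIRNA_LEN_MAX = 25, 30


@dataclass(frozen=True)
class AnnotationRecord:
    tag_id: str
    label: str
    evidence: str = ""

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class ReferenceSet:
    """A named FASTA reference collection of one ncRNA kind."""

    kind: str  # 'miRNA' | 'piRNA' | 'structural_ncRNA'
    records: List[Tuple[str, str]] = field(default_factory=list)  # (id, seq)

    @classmethod
    def from_fasta(cls, kind: str, path: str | Path) -> "ReferenceSet":
        recs = [
            (rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(kind, recs)

    def search(self, seq: str, max_mismatches: int = 0) -> Optional[str]:
        """Id of the first reference the tag is homologous to, else None."""
        for ref_id, ref in self.records:
            if _substring_match(seq, ref, max_mismatches) or _substring_match(
                seq, revcomp(ref), max_mismatches
            ):
                return ref_id
        return None


def _substring_match(query: str, subject: str, max_mismatches: int) -> bool:
    if max_mismatches == 0:
        return query in subject
    lq = len(query)
    for i in range(len(subject) - lq + 1):
        mm = sum(1 for a, b in zip(query, subject[i : i + lq]) if a != b)
        if mm <= max_mismatches:
            return True
    return False


def is_homologous(tag_seq: str, ref_seq: str, max_mismatches: int = 0) -> bool:
    """True iff the tag occurs in the reference or its reverse complement."""
    return _substring_match(tag_seq, ref_seq, max_mismatches) or _substring_match(
        tag_seq, revcomp(ref_seq), max_mismatches
    )


def annotate_tiers(
    tags: Iterable,
    refs: Dict[str, ReferenceSet],
    max_mismatches: int = 0,
) -> Dict[str, AnnotationRecord]:
    """Assign one tier label per tag (keyed by tag_id).

    ``refs`` maps kind -> ReferenceSet for 'structural_ncRNA', 'miRNA' and
    'piRNA'. An absent or empty reference set skips that homology tier with
    a warning; the length rules still apply.
    """
    for kind in ("structural_ncRNA", "miRNA", "piRNA"):
        if kind not in refs or not refs[kind].records:
            log.warning("reference set %r empty; homology tier skipped", kind)

    out: Dict[str, AnnotationRecord] = {}
    for tag in tags:
        seq, tid, n = tag.sequence, tag.tag_id, len(tag.sequence)
        rec = None
        struct = refs.get("structural_ncRNA")
        if struct and struct.records:
            ref_id = struct.search(seq, max_mismatches)
            if ref_id:
                rec = AnnotationRecord(tid, "structural_ncRNA", ref_id)
        if rec is None and MIRNA_MIN <= n <= MIRNA_MAX:
            mir = refs.get("miRNA")
            if mir and mir.records:
                ref_id = mir.search(seq, max_mismatches)
                if ref_id:
                    rec = AnnotationRecord(tid, "miRNA", ref_id)
        if rec is None:
            pir = refs.get("piRNA")
            ref_id = pir.search(seq, max_mismatches) if pir and pir.records else None
            if ref_id:
                rec = AnnotationRecord(tid, "piRNA", ref_id)
            elif PIRNA_LEN_MIN <= n <= PIRNA_LEN_MAX:
                rec = AnnotationRecord(tid, "piRNA", f"length_{n}nt")
        if rec is None and CAND_MIN <= n <= CAND_MAX:
            rec = AnnotationRecord(tid, "endo_siRNA_candidate", f"length_{n}nt")
        if rec is None:
            rec = AnnotationRecord(tid, "unknown")
        out[tid] = rec
    return out


def write_annotations_tsv(
    annotations: Dict[str, AnnotationRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\tlabel\tevidence\n")
        for tid in sorted(annotations):
            a = annotations[tid]
            fh.write(f"{a.tag_id}\t{a.label}\t{a.evidence}\n")
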