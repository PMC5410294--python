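"""Perfect-match placement of tags on a reference sequence set.

Reproduces a bowtie ``-k1 -n0`` style contract: only exact matches count,
and a tag with several placements gets exactly one reported hit, the
minimum under the total order (chrom name lexicographic, start ascending,
``+`` before ``-``). The total order makes multi-mapper resolution
reproducible, which a ``-k1`` report is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

from Bio import SeqIO

from ._seq import revcomp

SEED_K = 12  # seed k-mer width of the exact-match index


@dataclass(frozen=True)
class GenomeHit:
    """One perfect-match placement of a tag (0-based, half-open)."""

    tag_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def order_key(self):
        return (self.chrom, self.start, 0 if self.strand == "+" else 1)


class ExactIndex:
    """Seed-and-verify exact substring index over a set of sequences.

    Positions overlapping ``N`` are never reported: queries are restricted
    to the plain ACGT alphabet and an N in the window breaks the exact
    comparison.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise ValueError("cannot index an empty genome")
        for name, seq in sequences.items():
            if set(seq) - set("ACGTN"):
                raise ValueError(f"{name}: sequence has non-ACGTN characters")
        self.sequences: Dict[str, str] = dict(sequences)
        self._chroms = sorted(self.sequences)
        self._seeds: Dict[str, List[tuple]] = {}
        for chrom in self._chroms:
            seq = self.sequences[chrom]
            for i in range(len(seq) - SEED_K + 1):
                kmer = seq[i : i + SEED_K]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((chrom, i))

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def find_all(self, query: str) -> List[GenomeHit]:
        """All exact placements of ``query`` on both strands, sorted."""
        if len(query) < SEED_K:
            raise ValueError(f"query shorter than seed width {SEED_K}")
        hits = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            for chrom, i in self._seeds.get(q[:SEED_K], ()):
                seq = self.sequences[chrom]
                if seq[i : i + len(q)] == q:
                    hits.append(
                        GenomeHit("", chrom, i, i + len(q), strand)
                    )
        hits.sort(key=GenomeHit.order_key)
        return hits


def build_index(genome: Mapping[str, str] | str | Path) -> ExactIndex:
    """Build an :class:`ExactIndex` from a dict or a FASTA path."""
    if isinstance(genome, (str, Path)):
        genome = read_fasta(genome)
    return ExactIndex(genome)


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def map_tag(tag, index: ExactIndex) -> Optional[GenomeHit]:
    """Map one tag; returns the minimal hit under the total order, or None.

    ``tag`` may be a :class:`~endosirna.preprocess.SmallRNATag` or a plain
    (tag_id, sequence) pair.
    """
    if hasattr(tag, "sequence"):
        tag_id, seq = tag.tag_id, tag.sequence
    else:
        tag_id, seq = tag
    hits = index.find_all(seq)
    if not hits:
        return None
    best = hits[0]
    return GenomeHit(tag_id, best.chrom, best.start, best.end, best.strand)


def map_tags(tags: Iterable, index: ExactIndex):
    """Map many tags; returns (hits dict by tag_id, list of unmapped ids)."""
    mapped: Dict[str, GenomeHit] = {}
    unmapped: List[str] = []
    for tag in tags:
        hit = map_tag(tag, index)
        tid = tag.tag_id if hasattr(tag, "tag_id") else tag[0]
        if hit is None:
            unmapped.append(tid)
        else:
            mapped[tid] = hit
    return mapped, unmapped


def write_hits_bed(
    hits: Mapping[str, GenomeHit], scores: Mapping[str, int], path: str | Path
) -> None:
    """6-column BED; score column carries the tag's total read count."""
    rows = sorted(hits.values(), key=GenomeHit.order_key)
    with open(path, "w") as fh:
        for h in rows:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.tag_id}\t"
                f"{scores.get(h.tag_id, 0)}\t{h.strand}\n"
            )
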