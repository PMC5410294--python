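"""Raw small-RNA reads to collapsed, filtered tags.

The filtering cascade follows the standard small-RNA bookkeeping for
single-end libraries: drop reads containing ambiguous bases, trim the 3'
adapter, drop reads outside the 18-30 nt window, collapse identical
sequences into tags with per-library counts, and finally drop tags whose
total count is at or below the low-count floor (<= 2 reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

from ._seq import is_dna, tag_id_for

log = logging.getLogger(__name__)

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30
MIN_ADAPTER_OVERLAP = 6
COUNT_FLOOR = 2  # tags with total count <= COUNT_FLOOR are discarded


class MalformedFastqError(ValueError):
    """Raised when a FASTQ record cannot be parsed; names the record index."""


@dataclass
class SmallRNATag:
    """A collapsed unique small-RNA sequence with per-library read counts."""

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not is_dna(self.sequence):
            raise ValueError(f"tag sequence is not plain DNA: {self.sequence!r}")
        if not (MIN_TAG_LEN <= len(self.sequence) <= MAX_TAG_LEN):
            raise ValueError(
                f"tag length {len(self.sequence)} outside "
                f"[{MIN_TAG_LEN}, {MAX_TAG_LEN}]"
            )

    @property
    def tag_id(self) -> str:
        return tag_id_for(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterStats:
    """Per-library read bookkeeping; input = surviving + sum of removals."""

    input_reads: int = 0
    removed_n: int = 0
    removed_length: int = 0
    removed_low_count: int = 0
    surviving_reads: int = 0

    def conserved(self) -> bool:
        return self.input_reads == (
            self.removed_n
            + self.removed_length
            + self.removed_low_count
            + self.surviving_reads
        )


def trim_adapter(read: str, adapter: str) -> str:
    """Remove the leftmost 3' adapter occurrence from ``read``.

    A match is a prefix of ``adapter`` (at least ``MIN_ADAPTER_OVERLAP`` nt)
    anchored at any position of the read; the match and everything 3' of it
    are removed. Reads without a match are returned unchanged. No mismatches
    are tolerated.
    """
    if not adapter:
        return read
    la, lr = len(adapter), len(read)
    for p in range(lr):
        k = min(la, lr - p)
        if k < MIN_ADAPTER_OVERLAP:
            break
        if read[p : p + k] == adapter[:k]:
            return read[:p]
    return read


def read_fastq(path: str | Path) -> Iterable[str]:
    """Yield read sequences from a 4-line FASTQ file.

    Raises :class:`MalformedFastqError` naming the (0-based) record index of
    the first malformed record.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 != 0:
        raise MalformedFastqError(
            f"{path}: truncated FASTQ record at index {len(lines) // 4}"
        )
    for idx in range(0, len(lines), 4):
        head, seq, plus, qual = lines[idx : idx + 4]
        rec = idx // 4
        if not head.startswith("@"):
            raise MalformedFastqError(f"{path}: record {rec}: header lacks '@'")
        if not plus.startswith("+"):
            raise MalformedFastqError(f"{path}: record {rec}: separator lacks '+'")
        if len(seq) != len(qual):
            raise MalformedFastqError(
                f"{path}: record {rec}: sequence/quality length mismatch"
            )
        yield seq.upper()


def filter_and_collapse(
    reads_per_library: Mapping[str, Iterable[str]],
    adapter: str,
    count_filter_scope: str = "total",
) -> Tuple[List[SmallRNATag], Dict[str, FilterStats]]:
    """Collapse raw reads into filtered :class:`SmallRNATag` objects.

    Parameters
    ----------
    reads_per_library
        Mapping from library name to an iterable of read sequences
        (e.g. the output of :func:`read_fastq`).
    adapter
        3' adapter sequence; empty string disables trimming.
    count_filter_scope
        ``"total"`` removes tags whose summed count across libraries is
        <= 2; ``"per-library"`` zeroes counts <= 2 per library first and
        then drops tags with no remaining counts.

    Returns
    -------
    tags, stats
        Surviving tags (sorted by sequence for determinism) and per-library
        :class:`FilterStats` satisfying the conservation identity.
    """
    if count_filter_scope not in ("total", "per-library"):
        raise ValueError(f"unknown count_filter_scope {count_filter_scope!r}")
    libs = list(reads_per_library)
    if len(libs) != len(set(libs)):
        raise ValueError("library names must be unique")

    counts: Dict[str, Dict[str, int]] = {}
    stats = {lib: FilterStats() for lib in libs}
    for lib in libs:
        st = stats[lib]
        for raw in reads_per_library[lib]:
            st.input_reads += 1
            if "N" in raw:
                st.removed_n += 1
                continue
            seq = trim_adapter(raw, adapter)
            if not (MIN_TAG_LEN <= len(seq) <= MAX_TAG_LEN):
                st.removed_length += 1
                continue
            counts.setdefault(seq, {l: 0 for l in libs})[lib] += 1

    tags: List[SmallRNATag] = []
    for seq in sorted(counts):
        per_lib = counts[seq]
        if count_filter_scope == "per-library":
            kept = {l: c for l, c in per_lib.items() if c > COUNT_FLOOR}
            for lib, c in per_lib.items():
                if c <= COUNT_FLOOR:
                    stats[lib].removed_low_count += c
            if not kept:
                continue
            per_lib = {l: kept.get(l, 0) for l in libs}
        else:
            if sum(per_lib.values()) <= COUNT_FLOOR:
                for lib, c in per_lib.items():
                    stats[lib].removed_low_count += c
                continue
        for lib, c in per_lib.items():
            stats[lib].surviving_reads += c
        tags.append(SmallRNATag(seq, dict(per_lib)))

    for lib, st in stats.items():
        assert st.conserved(), f"read bookkeeping broken for {lib}"
    log.info(
        "preprocess: %d libraries, %d surviving tags", len(libs), len(tags)
    )
    return tags, stats


def collapse_fastq_files(
    fastq_per_library: Mapping[str, str | Path],
    adapter: str,
    count_filter_scope: str = "total",
) -> Tuple[List[SmallRNATag], Dict[str, FilterStats]]:
    """File-level convenience wrapper around :func:`filter_and_collapse`."""
    return filter_and_collapse(
        {lib: read_fastq(p) for lib, p in fastq_per_library.items()},
        adapter,
        count_filter_scope,
    )


def write_tags_tsv(tags: List[SmallRNATag], libs: List[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\tsequence\t" + "\t".join(libs) + "\n")
        for t in tags:
            row = "\t".join(str(t.counts.get(l, 0)) for l in libs)
            fh.write(f"{t.tag_id}\t{t.sequence}\t{row}\n")


def write_tags_fasta(tags: List[SmallRNATag], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f">{t.tag_id}_x{t.total_count}\n{t.sequence}\n")
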