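"""Class summary tables (sequences and reads per sncRNA class per library).

Percentages are integers, rounded half away from zero, computed from the
counts; per-class counts always sum to the totals row by construction and
that identity is asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import pandas as pd

SUMMARY_CLASSES = ("miRNA", "piRNA", "endo_siRNA", "unknown")


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percentage(count: int, total: int) -> int:
    return round_half_away(100.0 * count / total) if total > 0 else 0


@dataclass
class ClassSummary:
    """Per-library class x (sequences, reads) table with totals."""

    libraries: List[str]
    sequences: Dict[str, Dict[str, int]] = field(default_factory=dict)
    reads: Dict[str, Dict[str, int]] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls,
        sequences: Mapping[str, Mapping[str, int]],
        reads: Mapping[str, Mapping[str, int]],
        libraries: Sequence[str],
    ) -> "ClassSummary":
        s = cls(list(libraries))
        for lib in libraries:
            s.sequences[lib] = {c: int(sequences[lib].get(c, 0)) for c in SUMMARY_CLASSES}
            s.reads[lib] = {c: int(reads[lib].get(c, 0)) for c in SUMMARY_CLASSES}
        return s

    def total_sequences(self, lib: str) -> int:
        return sum(self.sequences[lib].values())

    def total_reads(self, lib: str) -> int:
        return sum(self.reads[lib].values())

    def sequence_pct(self, lib: str, cls_name: str) -> int:
        return percentage(self.sequences[lib][cls_name], self.total_sequences(lib))

    def read_pct(self, lib: str, cls_name: str) -> int:
        return percentage(self.reads[lib][cls_name], self.total_reads(lib))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls_name in SUMMARY_CLASSES + ("total",):
            row: Dict[str, object] = {"class": cls_name}
            for lib in self.libraries:
                if cls_name == "total":
                    row[f"{lib}_sequences"] = self.total_sequences(lib)
                    row[f"{lib}_sequences_pct"] = 100 if self.total_sequences(lib) else 0
                    row[f"{lib}_reads"] = self.total_reads(lib)
                    row[f"{lib}_reads_pct"] = 100 if self.total_reads(lib) else 0
                else:
                    row[f"{lib}_sequences"] = self.sequences[lib][cls_name]
                    row[f"{lib}_sequences_pct"] = self.sequence_pct(lib, cls_name)
                    row[f"{lib}_reads"] = self.reads[lib][cls_name]
                    row[f"{lib}_reads_pct"] = self.read_pct(lib, cls_name)
            rows.append(row)
        return pd.DataFrame(rows).set_index("class")

    def check_bookkeeping(self) -> None:
        """Class counts must sum to totals (trivially true, asserted as a
        guard against future aggregation bugs)."""
        for lib in self.libraries:
            assert self.total_sequences(lib) == sum(
                self.sequences[lib][c] for c in SUMMARY_CLASSES
            )
            assert self.total_reads(lib) == sum(
                self.reads[lib][c] for c in SUMMARY_CLASSES
            )


def summarize(final_annotations: Mapping, tags: Iterable, libraries: Sequence[str]) -> ClassSummary:
    """Aggregate final labels into the class summary.

    Structural ncRNA tags are excluded from the four-class table (they are
    identified and set aside before endo-siRNA classification, and the
    summary follows that accounting).
    """
    by_id = {t.tag_id: t for t in tags}
    seqs: Dict[str, Dict[str, int]] = {l: {c: 0 for c in SUMMARY_CLASSES} for l in libraries}
    reads: Dict[str, Dict[str, int]] = {l: {c: 0 for c in SUMMARY_CLASSES} for l in libraries}
    for tid, ann in final_annotations.items():
        if ann.label == "structural_ncRNA":
            continue
        if ann.label not in SUMMARY_CLASSES:
            raise ValueError(f"unexpected final label {ann.label!r}")
        tag = by_id[tid]
        for lib in libraries:
            c = tag.counts.get(lib, 0)
            if c > 0:
                seqs[lib][ann.label] += 1
                reads[lib][ann.label] += c
    summary = ClassSummary.from_counts(seqs, reads, libraries)
    summary.check_bookkeeping()
    return summary


def write_summary(summary: ClassSummary, tsv_path: str | Path, md_path: str | Path | None = None) -> None:
    frame = summary.to_frame()
    frame.to_csv(tsv_path, sep="\t")
    if md_path is not None:
        lines = ["# sncRNA class summary", ""]
        header = ["class"]
        for lib in summary.libraries:
            header += [f"{lib} sequences (%)", f"{lib} reads (%)"]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for cls_name in SUMMARY_CLASSES + ("total",):
            row = [cls_name]
            for lib in summary.libraries:
                if cls_name == "total":
                    row.append(f"{summary.total_sequences(lib)} (100)")
                    row.append(f"{summary.total_reads(lib)} (100)")
                else:
                    row.append(
                        f"{summary.sequences[lib][cls_name]} "
                        f"({summary.sequence_pct(lib, cls_name)})"
                    )
                    row.append(
                        f"{summary.reads[lib][cls_name]} "
                        f"({summary.read_pct(lib, cls_name)})"
                    )
            lines.append("| " + " | ".join(row) + " |")
        Path(md_path).write_text("\n".join(lines) + "\n")
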