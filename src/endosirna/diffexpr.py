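"""Differential-abundance screen for stage-enriched endo-siRNAs.

The screen selects tags enriched in a focal library (the zygote) relative
to every comparator library (sperm and oocyte), requiring a fold
difference strictly above 2 and a two-sided Fisher exact p strictly below
0.01 against each comparator. Counts are normalized as counts-per-million
with a 0.5 pseudocount so folds stay finite; no multiple-testing
correction is applied by default (the screen is a raw-threshold filter),
with an optional Benjamini-Hochberg flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

FOLD_THRESHOLD = 2.0
P_THRESHOLD = 0.01


@dataclass(frozen=True)
class DiffResult:
    tag_id: str
    library_a: str
    library_b: str
    cpm_a: float
    cpm_b: float
    fold: float  # a over b
    p_value: float
    selected: bool


def cpm(count: int, library_total: int) -> float:
    """Counts-per-million with a 0.5 pseudocount on count and total."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return (count + 0.5) / (library_total + 0.5) * 1e6


def exact_enrichment_test(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> float:
    """Two-sided Fisher exact p for the 2x2 table
    [[count_a, total_a - count_a], [count_b, total_b - count_b]]."""
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must satisfy 0 <= count <= total")
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def select_enriched(
    tags: Iterable,
    totals: Mapping[str, int],
    focal: str,
    comparators: Sequence[str],
    fold_threshold: float = FOLD_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    bh_correct: bool = False,
) -> Tuple[List[str], List[DiffResult]]:
    """Run the screen.

    A tag is selected iff for EVERY comparator the fold (focal cpm over
    comparator cpm) is strictly above ``fold_threshold`` and the Fisher p
    is strictly below ``p_threshold``. With ``bh_correct`` the p values
    are Benjamini-Hochberg adjusted per comparator before thresholding.

    Returns (selected tag ids, all per-pair DiffResults).
    """
    if not comparators:
        raise ValueError("at least one comparator library required")
    if fold_threshold <= 0:
        raise ValueError("fold threshold must be positive")
    tags = list(tags)
    results: List[DiffResult] = []
    pass_map: Dict[str, Dict[str, bool]] = {}
    for comp in comparators:
        pvals = []
        rows = []
        for tag in tags:
            ca = tag.counts.get(focal, 0)
            cb = tag.counts.get(comp, 0)
            cpm_a = cpm(ca, totals[focal])
            cpm_b = cpm(cb, totals[comp])
            fold = cpm_a / cpm_b
            p = exact_enrichment_test(ca, totals[focal], cb, totals[comp])
            pvals.append(p)
            rows.append((tag.tag_id, cpm_a, cpm_b, fold))
        pvals = np.asarray(pvals)
        effective = _bh_adjust(pvals) if bh_correct else pvals
        for (tid, cpm_a, cpm_b, fold), p_raw, p_eff in zip(rows, pvals, effective):
            ok = fold > fold_threshold and p_eff < p_threshold
            pass_map.setdefault(tid, {})[comp] = ok
            results.append(
                DiffResult(tid, focal, comp, cpm_a, cpm_b, fold, float(p_raw), ok)
            )
    selected = sorted(
        tid for tid, per_comp in pass_map.items() if all(per_comp.values())
    )
    return selected, results


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def write_diff_tsv(results: Sequence[DiffResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "tag_id\tfocal\tcomparator\tcpm_focal\tcpm_comparator\t"
            "fold\tp_value\tpassed\n"
        )
        for r in sorted(results, key=lambda r: (r.tag_id, r.library_b)):
            fh.write(
                f"{r.tag_id}\t{r.library_a}\t{r.library_b}\t{r.cpm_a:.4f}\t"
                f"{r.cpm_b:.4f}\t{r.fold:.6g}\t{r.p_value:.6g}\t"
                f"{int(r.selected)}\n"
            )
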