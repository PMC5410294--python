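"""Local sequence alignment used by the inverted-repeat and antisense
homology searches.

A hand-rolled Smith-Waterman with affine gaps is used instead of a library
aligner for two reasons:

* both searches need *suboptimal* non-overlapping local alignments
  (Waterman-Eggert style: extract the best alignment, mask its positions,
  re-align), not only the co-optimal set of the single best score;
* the self-versus-reverse-complement comparison needs a half-matrix
  restriction. Aligning an mRNA built as ``S + spacer + revcomp(S)``
  against its own reverse complement admits a spurious full-length
  "bridge" alignment (both arms match themselves across the spacer) that
  outscores the true inverted repeat; forbidding cells where the target
  position is not strictly upstream of the mirrored query position removes
  the bridge and every mirror-duplicate alignment while keeping every true
  inverted repeat (the last cell of any surviving alignment guarantees the
  two arm projections are disjoint and ordered).

Scoring convention: a gap of length ``k`` scores ``gap_open + k*gap_ext``
(both negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from numba import njit

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
NEG = -1.0e9


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq], dtype=np.int8)


@dataclass(frozen=True)
class LocalAlignment:
    """One gapped local alignment between target and query (0-based,
    half-open intervals on each)."""

    t_start: int
    t_end: int
    q_start: int
    q_end: int
    score: float
    matches: int
    columns: int  # aligned columns including gap columns

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@njit(cache=True)
def _sw_fill(t, q, match, mismatch, gap_open, gap_ext, tmask, qmask, half):
    n = t.shape[0]
    m = q.shape[0]
    M = np.zeros((n + 1, m + 1), np.float32)
    Ix = np.full((n + 1, m + 1), NEG, np.float32)
    Iy = np.full((n + 1, m + 1), NEG, np.float32)
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        if tmask[i - 1]:
            continue
        for j in range(1, m + 1):
            if qmask[j - 1]:
                continue
            if half and (i - 1) + (j - 1) >= n - 1:
                break
            # gap states
            op = M[i - 1, j] + gap_open + gap_ext
            ex = Ix[i - 1, j] + gap_ext
            if op >= ex:
                Ix[i, j] = op
                pX[i, j] = 1
            else:
                Ix[i, j] = ex
                pX[i, j] = 2
            op = M[i, j - 1] + gap_open + gap_ext
            ex = Iy[i, j - 1] + gap_ext
            if op >= ex:
                Iy[i, j] = op
                pY[i, j] = 1
            else:
                Iy[i, j] = ex
                pY[i, j] = 2
            # match state
            if t[i - 1] < 4 and t[i - 1] == q[j - 1]:
                s = match
            else:
                s = mismatch
            diag = M[i - 1, j - 1]
            src = 1
            if Ix[i - 1, j - 1] > diag:
                diag = Ix[i - 1, j - 1]
                src = 2
            if Iy[i - 1, j - 1] > diag:
                diag = Iy[i - 1, j - 1]
                src = 3
            v = diag + s
            if v <= 0.0:
                M[i, j] = 0.0
                pM[i, j] = 0
            else:
                M[i, j] = v
                # a zero-score diagonal M predecessor means the local
                # alignment starts in this cell
                pM[i, j] = 0 if (src == 1 and diag == 0.0) else src
                if v > best:
                    best = v
                    bi = i
                    bj = j
    return best, bi, bj, pM, pX, pY


def _traceback(t, q, bi, bj, pM, pX, pY) -> LocalAlignment:
    i, j = bi, bj
    state = 0  # 0 = M, 1 = Ix, 2 = Iy
    matches = 0
    columns = 0
    t_end, q_end = i, j
    while True:
        if state == 0:
            src = pM[i, j]
            columns += 1
            if t[i - 1] == q[j - 1] and t[i - 1] < 4:
                matches += 1
            i -= 1
            j -= 1
            if src == 0:
                break
            state = {1: 0, 2: 1, 3: 2}[int(src)]
        elif state == 1:
            src = pX[i, j]
            columns += 1
            i -= 1
            state = 0 if src == 1 else 1
        else:
            src = pY[i, j]
            columns += 1
            j -= 1
            state = 0 if src == 1 else 2
    return LocalAlignment(i, t_end, j, q_end, 0.0, matches, columns)


def local_align_best(
    target: str,
    query: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_ext: float = -2.0,
    tmask: Optional[np.ndarray] = None,
    qmask: Optional[np.ndarray] = None,
    half_matrix: bool = False,
) -> Optional[LocalAlignment]:
    """Best-scoring local alignment, or None if no positive-score cell."""
    t = encode(target)
    q = encode(query)
    if tmask is None:
        tmask = np.zeros(len(t), np.bool_)
    if qmask is None:
        qmask = np.zeros(len(q), np.bool_)
    best, bi, bj, pM, pX, pY = _sw_fill(
        t, q, match, mismatch, gap_open, gap_ext, tmask, qmask, half_matrix
    )
    if best <= 0.0:
        return None
    aln = _traceback(t, q, bi, bj, pM, pX, pY)
    return LocalAlignment(
        aln.t_start, aln.t_end, aln.q_start, aln.q_end, float(best),
        aln.matches, aln.columns,
    )


def local_align_all(
    target: str,
    query: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_ext: float = -2.0,
    min_length: int = 30,
    min_identity: float = 0.8,
    half_matrix: bool = False,
    max_hits: int = 64,
) -> List[LocalAlignment]:
    """Non-overlapping local alignments passing the length/identity filter.

    Waterman-Eggert style: repeatedly take the best alignment and mask its
    target and query positions, until the best score drops below the
    smallest score a qualifying alignment could have.
    """
    # a qualifying alignment has >= ceil(min_identity*min_length) matches
    min_matches = int(np.ceil(min_identity * min_length))
    stop_score = min_matches * match + (min_length - min_matches) * mismatch
    tmask = np.zeros(len(target), np.bool_)
    qmask = np.zeros(len(query), np.bool_)
    out: List[LocalAlignment] = []
    for _ in range(max_hits):
        aln = local_align_best(
            target, query, match, mismatch, gap_open, gap_ext,
            tmask, qmask, half_matrix,
        )
        if aln is None or aln.score < stop_score:
            break
        tmask[aln.t_start : aln.t_end] = True
        qmask[aln.q_start : aln.q_end] = True
        if aln.columns >= min_length and aln.identity >= min_identity:
            out.append(aln)
    return out
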