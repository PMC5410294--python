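"""RNA secondary structure by base-pair maximization (Nussinov).

The hairpin decision the pipeline needs is "does this cluster region fold
back on itself with two long arms", for which counting Watson-Crick plus
G.U wobble pairs under the usual nesting constraints is sufficient; free
energies in kcal/mol are deliberately out of scope. Minimum hairpin loop
is 3 (a pair (i, j) requires j - i >= 4), pairs are strictly nested.

Arms are derived from the traceback: the longest contiguous helix is
extended over directly stacked neighbouring helices whose interior gaps
are at most 4 unpaired positions on both strands; the two strands of the
extended helix chain are the 5' and 3' arms and the enclosed segment is
the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from ._seq import is_dna

MIN_LOOP = 3
MAX_ARM_GAP = 4  # unpaired positions tolerated between stacked helices

# allowed pairs (DNA alphabet standing in for RNA): A-T, G-C, G-T wobble
_CAN_PAIR = np.zeros((4, 4), np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _CAN_PAIR[_a, _b] = True

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class HairpinStructure:
    region: str
    pairs: List[Tuple[int, int]]
    arm5: Optional[Tuple[int, int]] = None  # half-open interval
    arm3: Optional[Tuple[int, int]] = None
    loop: Optional[Tuple[int, int]] = None
    helices: List[Tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def paired_fraction(self) -> float:
        return 2 * len(self.pairs) / len(self.region) if self.region else 0.0

    def arm_lengths(self) -> Tuple[int, int]:
        a5 = self.arm5[1] - self.arm5[0] if self.arm5 else 0
        a3 = self.arm3[1] - self.arm3[0] if self.arm3 else 0
        return a5, a3


@njit(cache=True)
def _nussinov_dp(x):
    n = x.shape[0]
    N = np.zeros((n, n), np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1, j]
            if N[i, j - 1] > best:
                best = N[i, j - 1]
            if _CAN_PAIR[x[i], x[j]]:
                v = N[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = N[i, k] + N[k + 1, j]
                if v > best:
                    best = v
            N[i, j] = best
    return N


def _traceback(x: np.ndarray, N: np.ndarray) -> List[Tuple[int, int]]:
    """Recover one optimal structure, preferring to pair the outermost
    positions whenever that choice is optimal (keeps long stems intact)."""
    pairs: List[Tuple[int, int]] = []
    stack = [(0, x.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if _CAN_PAIR[x[i], x[j]] and N[i, j] == N[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if N[i, j] == N[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if N[i, j] == N[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j):
            if N[i, k] + N[k + 1, j] == N[i, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    pairs.sort()
    return pairs


def _helices(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int, int, int]]:
    """Group pairs into maximal stacked helices (i0, i1, j0, j1):
    pairs (i0 + t, j1 - t) for t in 0..(i1 - i0)."""
    out = []
    run: List[Tuple[int, int]] = []
    for p in pairs:
        if run and (p[0] == run[-1][0] + 1 and p[1] == run[-1][1] - 1):
            run.append(p)
        else:
            if run:
                out.append((run[0][0], run[-1][0], run[-1][1], run[0][1]))
            run = [p]
    if run:
        out.append((run[0][0], run[-1][0], run[-1][1], run[0][1]))
    return out


def _stacks(a, b) -> bool:
    """True if helix ``b`` is directly nested inside helix ``a`` with at
    most MAX_ARM_GAP unpaired positions on each strand."""
    return (
        0 < b[0] - a[1] <= MAX_ARM_GAP + 1
        and 0 < a[2] - b[3] <= MAX_ARM_GAP + 1
        and b[3] < a[2]
    )


def _arm_chain(helices):
    """Chain containing the longest helix, extended outward and inward."""
    if not helices:
        return None
    longest = max(helices, key=lambda h: h[1] - h[0])
    chain = [longest]
    grew = True
    while grew:
        grew = False
        for h in helices:
            if h in chain:
                continue
            if _stacks(h, chain[0]):  # h encloses current outer end
                chain.insert(0, h)
                grew = True
            elif _stacks(chain[-1], h):  # h nests inside current inner end
                chain.append(h)
                grew = True
    return chain


def fold_region(region: str) -> HairpinStructure:
    """Fold one cluster region and locate its arms.

    Preconditions: 40 <= length <= 20000, plain ACGT.
    """
    n = len(region)
    if not MIN_LOOP + 2 <= n <= 20000:
        raise ValueError(f"region length {n} outside foldable range")
    if not is_dna(region):
        raise ValueError("region contains characters outside ACGT")
    x = np.array([_CODE[c] for c in region], dtype=np.int8)
    N = _nussinov_dp(x)
    pairs = _traceback(x, N)
    assert len(pairs) == int(N[0, n - 1]), "traceback lost pairs"
    structure = HairpinStructure(region, pairs)
    structure.helices = _helices(pairs)
    chain = _arm_chain(structure.helices)
    if chain:
        outer, inner = chain[0], chain[-1]
        structure.arm5 = (outer[0], inner[1] + 1)
        structure.arm3 = (inner[2], outer[3] + 1)
        structure.loop = (inner[1] + 1, inner[2])
    return structure
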