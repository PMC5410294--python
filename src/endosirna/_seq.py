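"""Small sequence helpers shared across the package."""

from __future__ import annotations

import hashlib

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, allow_n: bool = False) -> bool:
    alphabet = set("ACGTN" if allow_n else "ACGT")
    return len(seq) > 0 and set(seq) <= alphabet


def tag_id_for(seq: str) -> str:
    """Stable identifier derived from the tag sequence alone."""
    return "tag_" + hashlib.sha1(seq.encode()).hexdigest()[:12]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=length))


def mutate_base(rng: np.random.Generator, base: str) -> str:
    """Return a uniformly chosen base different from ``base``."""
    choices = [b for b in DNA if b != base]
    return choices[int(rng.integers(0, 3))]


def comp_base(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}[base]
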