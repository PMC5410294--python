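"""Promoter coordinates, upstream extraction, antisense homology and the
asL1 dsRNA duplex model."""

import numpy as np
import pytest

from endosirna._seq import random_dna, revcomp
from endosirna.l1asp import (
    HomologyBlock,
    UpstreamFlank,
    assign_l1_sirnas,
    build_duplex,
    extract_upstream,
    find_homology,
    fold_change_ddct,
    offset_to_promoter,
    promoter_to_offset,
    span_length,
    spliced_product_length,
)
from endosirna.mapping import GenomeHit


# --------------------------------------------------- promoter coordinates

def test_coordinate_anchors():
    tss = 5000
    assert promoter_to_offset(1, tss, "+") == tss  # +1 is the TSS base
    assert promoter_to_offset(-1, tss, "+") == tss - 1  # first upstream base
    assert promoter_to_offset(2, tss, "+") == tss + 1
    assert promoter_to_offset(1, tss, "-") == tss
    assert promoter_to_offset(-1, tss, "-") == tss + 1
    with pytest.raises(ValueError):
        promoter_to_offset(0, tss, "+")


def test_coordinate_round_trip_bijection():
    rng = np.random.default_rng(0)
    tss = 10_000
    for strand in "+-":
        offsets = rng.integers(0, 20_000, size=1000)
        for off in offsets:
            c = offset_to_promoter(int(off), tss, strand)
            assert c != 0
            assert promoter_to_offset(c, tss, strand) == off
    # and coord -> offset -> coord over +/- 1e4
    for strand in "+-":
        for c in list(range(-10_000, 0)) + list(range(1, 10_001)):
            off = promoter_to_offset(c, tss, strand)
            assert offset_to_promoter(off, tss, strand) == c


def test_span_length_no_zero():
    assert span_length((93, -490)) == 583  # no position 0 to count
    assert span_length((-1, -365)) == 365
    assert span_length((1, 1)) == 1


# -------------------------------------------------------------- upstream

def test_extract_upstream_strands_and_truncation():
    rng = np.random.default_rng(1)
    chrom = random_dna(rng, 10_000)
    genome = {"c": chrom}
    bed = [
        ("c", 5000, 8000, "plus", 0, "+"),
        ("c", 100, 900, "minus", 0, "-"),
        ("c", 100, 600, "short_plus", 0, "+"),
    ]
    flanks = {f.l1_id: f for f in extract_upstream(genome, bed, window=3000)}
    assert flanks["plus"].sequence == chrom[2000:5000]
    assert not flanks["plus"].truncated
    # '-' strand: reverse complement of the 3000 nt 3' of the element end
    assert flanks["minus"].sequence == revcomp(chrom[900:3900])
    assert not flanks["minus"].truncated
    # chromosome start intervenes: truncated and flagged
    assert flanks["short_plus"].sequence == chrom[0:100]
    assert flanks["short_plus"].truncated


def test_bed_errors_carry_line_numbers(tmp_path):
    p = tmp_path / "l1.bed"
    p.write_text("c\t0\t100\tok\t0\t+\nc\tx\t200\tbad\t0\t+\n")
    with pytest.raises(ValueError, match="line 2"):
        extract_upstream({"c": "ACGT" * 100}, p)


# -------------------------------------------------------------- homology

def test_find_homology_planted_antisense_block():
    """An upstream flank ending in the exact reverse complement of a
    365-nt target sub-interval yields one block at -1..-365, identity 1."""
    rng = np.random.default_rng(2)
    target = random_dna(rng, 1800)
    sub = target[400:765]
    from endosirna._seq import comp_base

    flank_seq = random_dna(rng, 3000 - 365) + revcomp(sub)
    # guard the junction bases against chance extension of the alignment
    guarded = list(flank_seq)
    for k in range(3):
        bad = comp_base(target[765 + k])
        if guarded[2634 - k] == bad:
            guarded[2634 - k] = "A" if bad != "A" else "C"
    flank_seq = "".join(guarded)
    flank = UpstreamFlank("l1", "c", 0, 3000, "+", flank_seq)
    blocks = find_homology([flank], target, target_offset=1200)
    assert len(blocks) >= 1
    b = blocks[0]
    assert (b.upstream_from, b.upstream_to) == (-1, -365)
    assert (b.target_start, b.target_end) == (1600, 1965)
    assert b.identity == pytest.approx(1.0)
    assert b.orientation == "antisense"


def test_find_homology_random_flank_is_empty():
    rng = np.random.default_rng(3)
    target = random_dna(rng, 1000)
    flank = UpstreamFlank("l1", "c", 0, 3000, "+", random_dna(rng, 3000))
    assert find_homology([flank], target) == []


def test_homology_identity_reflects_mismatches():
    rng = np.random.default_rng(4)
    target = random_dna(rng, 500)
    sub = list(revcomp(target[100:200]))
    sub[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[50]]
    flank = UpstreamFlank("l1", "c", 0, 600, "+",
                          random_dna(rng, 500) + "".join(sub))
    blocks = find_homology([flank], target)
    assert blocks and blocks[0].identity == pytest.approx(0.99, abs=0.005)


# ---------------------------------------------------------------- duplex

def _block(up_from, up_to, t_start=1600):
    length = span_length((up_from, up_to))
    return HomologyBlock("l1", up_from, up_to, t_start, t_start + length,
                         2.0 * length, 1.0, length)


def test_duplex_full_block_within_span():
    d = build_duplex((93, -490), _block(-1, -365))
    assert d.length == 365
    assert d.active
    assert d.sense_interval == (1600, 1965)


def test_duplex_disjoint_span_is_inactive():
    d = build_duplex((93, -100), _block(-200, -365))
    assert d.length == 0 and not d.active


def test_duplex_partial_overlap_matches_enumeration():
    """Duplex length equals explicit position-by-position enumeration."""
    span, block = (93, -200), (-1, -365)
    d = build_duplex(span, _block(*block))
    span_positions = set(range(-200, 0)) | set(range(1, 94))
    block_positions = set(range(-365, 0))
    assert d.length == len(span_positions & block_positions) == 200
    # symmetry in interval order; never exceeds either interval
    d2 = build_duplex((-200, 93), _block(-365, -1))
    assert d2.length == d.length
    assert d.length <= span_length(span)
    assert d.length <= span_length(block)


def test_assign_l1_sirnas_containment_and_strand():
    d = build_duplex((93, -490), _block(-1, -365))
    hits = {
        "s1": GenomeHit("s1", "L1", 1610, 1632, "+"),
        "a1": GenomeHit("a1", "L1", 1700, 1722, "-"),
        "edge": GenomeHit("edge", "L1", 1944, 1966, "+"),  # 1 nt outside
        "out": GenomeHit("out", "L1", 500, 522, "+"),
    }
    assigned = assign_l1_sirnas(hits, d)
    assert dict(assigned) == {"s1": "sense", "a1": "antisense"}
    assert d.assigned == assigned


# ------------------------------------------------------ assay arithmetic

def test_spliced_product_arithmetic():
    assert spliced_product_length(1313, 960) == 353
    assert spliced_product_length(500, 200) == 300
    assert spliced_product_length(500, 0) == 500
    with pytest.raises(ValueError):
        spliced_product_length(500, 500)


def test_ddct_fold_change():
    assert fold_change_ddct(20, 15, 22, 17) == pytest.approx(1.0)
    assert fold_change_ddct(21, 15, 22, 17) == pytest.approx(0.5)
    assert fold_change_ddct(20, 15, 24, 17) == pytest.approx(4.0)
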