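"""TE / cluster / hairpin / inverted-complement classification rules."""

import numpy as np
import pytest

from endosirna._seq import random_dna, revcomp
from endosirna.annotate import AnnotationRecord
from endosirna.classify import (
    EndoSiRNACall,
    ICRegion,
    SiRNACluster,
    assign_ic,
    classify_lhp,
    classify_te,
    finalize_labels,
    find_clusters,
    find_inverted_complement,
    read_repeat_library,
)
from endosirna.fold import HairpinStructure, fold_region
from endosirna.mapping import GenomeHit


class Tag:
    def __init__(self, tag_id, sequence):
        self.tag_id = tag_id
        self.sequence = sequence


# ------------------------------------------------------------------ TE

REPEATS = [
    ("ltr_1", "LTR", "ACGGTTACCGGATTACGGATCGGATCGATCGGGATTACCAGTCCAGTA"),
    ("l1_1", "L1", "TTGGCCAATTGGCCTTAACCGGTTAACCGGAATTCCGGAATTCCATGC"),
]


def test_classify_te_strand_family_and_order():
    cands = [
        Tag("a", REPEATS[1][2][5:27]),  # substring of the L1 record
        Tag("b", revcomp(REPEATS[0][2][10:32])),  # revcomp of the LTR record
        Tag("c", "ACGTACGTACGTACGTACGTAC"),  # matches nothing
    ]
    calls = {c.tag_id: c for c in classify_te(cands, REPEATS)}
    assert calls["a"].family == "L1" and calls["a"].locus == "l1_1"
    assert calls["b"].family == "LTR"
    assert "c" not in calls


def test_classify_te_tie_first_record_wins():
    shared = "ACGGATCCTAGGCATCGATTGGCA"
    reps = [("r1", "SINE", "AAAA" + shared), ("r2", "ERV", shared + "TTTT")]
    calls = classify_te([Tag("t", shared[:22])], reps)
    assert calls[0].family == "SINE" and calls[0].locus == "r1"


def test_repeat_library_requires_family_tags(tmp_path):
    p = tmp_path / "reps.fasta"
    p.write_text(">rep1 family=LTR\nACGT\n>rep2 nofamily\nACGT\n")
    with pytest.raises(ValueError, match="rep2"):
        read_repeat_library(p)


# ------------------------------------------------------------- clusters

def _hits(starts, chrom="c", length=22):
    return [
        GenomeHit(f"t{i}", chrom, s, s + length, "+") for i, s in enumerate(starts)
    ]


def _seqs(hits):
    # distinct sequence per tag id
    return {h.tag_id: f"seq_{h.tag_id}" for h in hits}


def oracle_cluster_members(hits, seqs, max_span=10000, min_unique=16):
    """Exhaustive window enumeration: members of every maximal run of
    consecutive hits with span < max_span and >= min_unique sequences."""
    hits = sorted(hits, key=lambda h: (h.chrom, h.start, h.end))
    members = set()
    n = len(hits)
    for i in range(n):
        for j in range(i, n):
            window = hits[i : j + 1]
            if any(h.chrom != hits[i].chrom for h in window):
                break
            span = max(h.end for h in window) - window[0].start
            if span >= max_span:
                break
            extendable = (
                j + 1 < n
                and hits[j + 1].chrom == hits[i].chrom
                and max(max(h.end for h in window), hits[j + 1].end)
                - window[0].start
                < max_span
            )
            if extendable:
                continue
            if len({seqs[h.tag_id] for h in window}) >= min_unique:
                members.update(h.tag_id for h in window)
    return members


def test_cluster_boundaries():
    # 16 distinct tags spanning 9,999 nt -> one cluster
    starts = list(np.linspace(0, 9999 - 22, 16).astype(int))
    hits = _hits(starts)
    assert hits[-1].end == 9999
    clusters = find_clusters(hits, _seqs(hits))
    assert len(clusters) == 1 and clusters[0].distinct_sequences == 16
    assert clusters[0].span == 9999

    # 15 distinct tags in 1 kb -> below the uniqueness threshold
    hits = _hits(list(np.linspace(0, 978, 15).astype(int)))
    assert find_clusters(hits, _seqs(hits)) == []

    # 16 distinct tags spanning exactly 10,000 nt -> no cluster
    starts = list(np.linspace(0, 10000 - 22, 16).astype(int))
    hits = _hits(starts)
    assert hits[-1].end == 10000
    assert find_clusters(hits, _seqs(hits)) == []


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clusters_match_window_oracle(seed):
    """Well-separated random clusters on a <= 20 kb span: greedy cluster
    membership equals exhaustive maximal-window enumeration."""
    rng = np.random.default_rng(seed)
    starts = sorted(rng.integers(0, 3000, size=20).tolist())
    starts += sorted((15000 + rng.integers(0, 2500, size=18)).tolist())
    hits = _hits(starts)
    seqs = _seqs(hits)
    clusters = find_clusters(hits, seqs)
    got = {tid for c in clusters for tid in c.member_tag_ids}
    assert got == oracle_cluster_members(hits, seqs)
    for c in clusters:
        assert c.span < 10000 and c.distinct_sequences >= 16


def test_duplicate_sequences_do_not_count_twice():
    hits = _hits(list(np.linspace(0, 2000, 20).astype(int)))
    seqs = _seqs(hits)
    for i in range(5):  # collapse five sequences onto others
        seqs[f"t{i}"] = seqs[f"t{i + 5}"]
    assert find_clusters(hits, seqs) == []  # 15 distinct < 16


# ------------------------------------------------------------------ Lhp

def test_classify_lhp_containment_and_qualification():
    rng = np.random.default_rng(1)
    arm, loop = 60, 30
    # poly-A loop cannot pair, so the folded arms are exactly the stem
    region = random_dna(rng, arm)
    region = region + "A" * loop + revcomp(region[:arm])
    structure = fold_region(region)
    cluster = SiRNACluster("c", 1000, 1000 + len(region),
                           ["in5", "in3", "straddle"], 16, "cl1")
    hits = {
        "in5": GenomeHit("in5", "c", 1005, 1027, "+"),
        "in3": GenomeHit("in3", "c", 1000 + arm + loop + 5,
                         1000 + arm + loop + 27, "+"),
        "straddle": GenomeHit("straddle", "c", 1000 + arm - 10,
                              1000 + arm + 12, "+"),  # spans arm/loop boundary
    }
    calls = classify_lhp(cluster, structure, hits, {"in5", "in3", "straddle"})
    assert {c.tag_id for c in calls} == {"in5", "in3"}
    assert all(c.subclass == "Lhp" and c.locus == "cl1" for c in calls)

    # low paired fraction disqualifies the region outright
    weak = HairpinStructure("A" * 100, [(0, 99), (1, 98)],
                            arm5=(0, 25), arm3=(75, 100), loop=(25, 75))
    assert weak.paired_fraction < 0.5
    assert classify_lhp(cluster, weak, hits, {"in5", "in3"}) == []

    # short arms disqualify even a well-paired region
    calls = classify_lhp(cluster, structure, hits, {"in5", "in3"}, min_arm=200)
    assert calls == []


def test_classify_lhp_ignores_non_candidates():
    rng = np.random.default_rng(2)
    arm = random_dna(rng, 60)
    region = arm + random_dna(rng, 30) + revcomp(arm)
    structure = fold_region(region)
    cluster = SiRNACluster("c", 0, len(region), ["x"], 16, "cl")
    hits = {"x": GenomeHit("x", "c", 5, 27, "+")}
    assert classify_lhp(cluster, structure, hits, candidates=set()) == []


# ------------------------------------------------------------------- IC

def test_ic_region_exact_inverted_repeat():
    rng = np.random.default_rng(0)
    S = random_dna(rng, 217)
    # A...A spacer ends cannot extend the arm-arm complementarity
    spacer = "AAA" + random_dna(rng, 94) + "AAA"
    mrna = S + spacer + revcomp(S)
    regions = find_inverted_complement("m", mrna)
    assert len(regions) == 1
    r = regions[0]
    assert r.region_length == 217
    assert r.identity == pytest.approx(1.0)
    assert r.arm1 == (0, 217)
    assert r.arm2 == (317, 534)


def test_ic_random_mrna_has_no_region():
    rng = np.random.default_rng(42)
    mrna = random_dna(rng, 500)
    assert find_inverted_complement("m", mrna) == []


def test_ic_perfect_palindrome_arms_adjacent():
    rng = np.random.default_rng(9)
    S = random_dna(rng, 40)
    regions = find_inverted_complement("m", S + revcomp(S))
    assert len(regions) == 1
    r = regions[0]
    assert r.arm1[1] <= r.arm2[0]  # adjacent, non-overlapping
    assert r.region_length >= 35


def test_ic_identity_recomputable_from_arms():
    """Reported identity matches direct recomputation from the arms."""
    rng = np.random.default_rng(5)
    S = random_dna(rng, 100)
    arm2 = list(revcomp(S))
    for pos in (20, 50, 80):
        arm2[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm2[pos]]
    mrna = S + "AAA" + random_dna(rng, 54) + "AAA" + "".join(arm2)
    regions = find_inverted_complement("m", mrna)
    assert regions
    r = regions[0]
    a1 = mrna[r.arm1[0] : r.arm1[1]]
    a2 = mrna[r.arm2[0] : r.arm2[1]]
    direct = sum(x == y for x, y in zip(a1, revcomp(a2))) / r.region_length
    assert r.identity == pytest.approx(direct)
    assert r.identity >= 0.8


def test_assign_ic_strict_containment():
    region = ICRegion("m", (0, 217), (317, 534), 217, 1.0, 434.0)
    hits = {
        "in1": GenomeHit("in1", "m", 5, 27, "+"),
        "in2": GenomeHit("in2", "m", 330, 352, "-"),
        "spacer": GenomeHit("spacer", "m", 250, 272, "+"),
        "half": GenomeHit("half", "m", 210, 232, "+"),  # arm1/spacer straddle
        "other": GenomeHit("other", "x", 5, 27, "+"),  # different mRNA
    }
    calls = assign_ic(hits, [region], set(hits))
    assert {c.tag_id for c in calls} == {"in1", "in2"}


# ------------------------------------------------------------- finalize

def _ann(tid, label="endo_siRNA_candidate"):
    return AnnotationRecord(tid, label)


def test_finalize_priority_and_unknown_fallback():
    annotations = {t: _ann(t) for t in ("a", "b", "c")}
    annotations["m"] = _ann("m", "miRNA")
    calls = [
        EndoSiRNACall("a", "TE", "L1", "rep"),
        EndoSiRNACall("a", "Lhp", "", "cl"),
        EndoSiRNACall("b", "IC", "", "m1"),
    ]
    final = finalize_labels(annotations, calls)
    assert final["a"].label == "endo_siRNA" and final["a"].subclass == "TE"
    assert final["b"].subclass == "IC"
    assert final["c"].label == "unknown"  # candidate with no call
    assert final["m"].label == "miRNA"  # non-candidates pass through


def test_endo_call_invariants():
    with pytest.raises(ValueError):
        EndoSiRNACall("t", "TE", "", "locus")  # TE requires a family
    with pytest.raises(ValueError):
        EndoSiRNACall("t", "Lhp", "L1", "locus")  # family only for TE
    with pytest.raises(ValueError):
        EndoSiRNACall("t", "Lhp", "", "")  # locus always set
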