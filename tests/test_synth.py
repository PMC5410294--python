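"""Toy genome construction and library simulation contracts."""

from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from endosirna._seq import revcomp
from endosirna.synth import (
    FeatureOverlapError,
    HairpinLocus,
    ICmRNA,
    L1Locus,
    ToyGenomeSpec,
    background_length_pmf,
    build_toy_genome,
    sample_background_lengths,
    simulate_libraries,
)


def test_hairpin_is_exact_inverted_repeat():
    spec = ToyGenomeSpec(
        genome_length=2000, seed=3, libraries=("z",),
        hairpin_loci=(HairpinLocus(arm=30, loop=10, position=500, tag_count=4),),
    )
    toy = build_toy_genome(spec)
    g = toy.genome["chr1"]
    region = g[500:570]
    assert region[40:70] == revcomp(region[0:30])  # 70-nt exact IR


def test_asp_block_is_revcomp_of_orf2_subinterval():
    spec = ToyGenomeSpec(genome_length=12000, seed=1, libraries=("z",),
                         l1_locus=L1Locus(position=4000))
    toy = build_toy_genome(spec)
    g = toy.genome["chr1"]
    sub = toy.l1_consensus[1600:1965]
    block = g[4000 - 365 : 4000]
    assert len(block) == 365
    assert block == revcomp(sub)


def test_overlapping_features_rejected_with_both_names():
    spec = ToyGenomeSpec(
        genome_length=5000, seed=0, libraries=("z",),
        hairpin_loci=(
            HairpinLocus(arm=50, loop=20, position=1000, tag_count=2),
            HairpinLocus(arm=50, loop=20, position=1050, tag_count=2),
        ),
    )
    with pytest.raises(FeatureOverlapError, match="hairpin_1.*hairpin_0"):
        build_toy_genome(spec)


def test_same_seed_same_bytes(tmp_path):
    spec = ToyGenomeSpec(
        genome_length=4000, seed=11, libraries=("a", "b"),
        ic_mrnas=(ICmRNA(arm=60, spacer=40, position=1000, tag_count=2),),
    )
    outs = []
    for run in ("r1", "r2"):
        toy = build_toy_genome(spec)
        paths = simulate_libraries(
            toy.genome, toy.truth, ["a", "b"], {"a": 500, "b": 500},
            seed=7, outdir=tmp_path / run, background_fraction=0.2,
        )
        outs.append({lib: Path(p).read_bytes() for lib, p in paths.items()})
    assert outs[0] == outs[1]
    toy1 = build_toy_genome(spec)
    toy2 = build_toy_genome(spec)
    assert toy1.genome == toy2.genome
    assert toy1.truth.equals(toy2.truth)


def test_multinomial_sampling_within_three_sigma(tmp_path):
    """Observed planted counts stay within 3 binomial standard deviations
    of the multinomial expectation."""
    spec = ToyGenomeSpec(
        genome_length=4000, seed=2, libraries=("zygote", "sperm"),
        ic_mrnas=(ICmRNA(arm=80, spacer=40, position=1000, tag_count=4),),
    )
    toy = build_toy_genome(spec)
    truth = toy.truth.copy()
    truth["zygote"] = [100, 10, 10, 10]
    truth["sperm"] = [10, 10, 10, 100]
    depth = 10_000
    paths = simulate_libraries(
        toy.genome, truth, ["zygote", "sperm"],
        {"zygote": depth, "sperm": depth},
        seed=5, outdir=tmp_path, background_fraction=0.0, adapter="",
    )
    for lib in ("zygote", "sperm"):
        reads = [
            l.strip() for i, l in enumerate(Path(paths[lib]).read_text().splitlines())
            if i % 4 == 1
        ]
        total_w = truth[lib].sum()
        for _, row in truth.iterrows():
            p = row[lib] / total_w
            expected = depth * p
            sd = np.sqrt(depth * p * (1 - p))
            observed = sum(r == row["sequence"] for r in reads)
            assert abs(observed - expected) <= 3 * sd + 1e-9


def test_zero_depth_and_empty_adapter(tmp_path):
    spec = ToyGenomeSpec(genome_length=2000, seed=4, libraries=("z",),
                         ic_mrnas=(ICmRNA(arm=60, spacer=40, position=500,
                                          tag_count=2),))
    toy = build_toy_genome(spec)
    paths = simulate_libraries(toy.genome, toy.truth, ["z"], {"z": 0},
                               seed=1, outdir=tmp_path / "d0")
    assert Path(paths["z"]).read_text() == ""  # depth 0: empty FASTQ
    paths = simulate_libraries(toy.genome, toy.truth, ["z"], {"z": 200},
                               seed=1, outdir=tmp_path / "noadapt",
                               background_fraction=0.0, adapter="")
    reads = [
        l for i, l in enumerate(Path(paths["z"]).read_text().splitlines())
        if i % 4 == 1
    ]
    planted = set(toy.truth["sequence"])
    assert reads and all(r in planted for r in reads)


def test_unknown_library_rejected(tmp_path):
    spec = ToyGenomeSpec(genome_length=2000, seed=4, libraries=("z",),
                         ic_mrnas=(ICmRNA(arm=60, spacer=40, position=500,
                                          tag_count=2),))
    toy = build_toy_genome(spec)
    with pytest.raises(ValueError, match="nope"):
        simulate_libraries(toy.genome, toy.truth, ["nope"], {"nope": 100},
                           seed=1, outdir=tmp_path)


def test_background_lengths_bimodal_chi_square():
    """Sampled background lengths match the configured discretized
    mixture (chi-square, alpha = 0.01, n = 1e5) and the pmf is bimodal
    with modes at 23 and 27-28 nt."""
    pmf = background_length_pmf()
    assert sum(pmf.values()) == pytest.approx(1.0, abs=1e-9)
    assert max(pmf, key=pmf.get) in (23, 27, 28)
    assert pmf[23] > pmf[25] < pmf[27]  # trough between the modes
    rng = np.random.default_rng(123)
    n = 100_000
    lengths = sample_background_lengths(rng, n)
    observed = np.array([(lengths == L).sum() for L in range(18, 31)])
    expected = np.array([pmf[L] * n for L in range(18, 31)])
    keep = expected > 5
    chi2, p = stats.chisquare(observed[keep], expected[keep] *
                              observed[keep].sum() / expected[keep].sum())
    assert p > 0.01


def test_planted_tags_exist_in_genome(study_result):
    toy = study_result.toy
    g = toy.genome["chr1"]
    for _, row in toy.truth.iterrows():
        assert row["sequence"] in g or revcomp(row["sequence"]) in g
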