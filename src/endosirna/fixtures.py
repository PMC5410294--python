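"""Packaged study fixtures: toy-genome specs whose planted composition
mirrors the described cluster structures, plus helpers that materialize
them to disk and run the pipeline on them.

The three focused fixtures reproduce, respectively:

* a long-hairpin siRNA cluster with 17 tags spread over a 1612-nt
  inverted-repeat locus (700-nt arms, 212-nt loop, lightly diverged 3'
  arm so reads map across both arms);
* an L1 locus whose upstream flank carries a 365-nt antisense copy of an
  ORF2 sub-interval, an asL1 transcript spanning +93..-490, 9 duplex tags
  (sense and antisense) and decoy tags outside the duplex;
* a Plce1-like mRNA with a 217-nt inverted-complement region, 2 in-arm
  tags and decoy tags in the spacer.

The full study fixture combines every feature class on one 120-kb toy
chromosome, with features spaced >= ~10 kb apart so that only the
planted hairpin reaches the cluster threshold. All fixtures simulate
noise-free exact-abundance libraries; backgrounds are exercised
separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

from . import pipeline as pl
from .synth import (
    DEFAULT_ADAPTER,
    GeneLocus,
    HairpinLocus,
    ICmRNA,
    L1Locus,
    TagSite,
    TECopy,
    ToyData,
    ToyGenomeSpec,
    build_toy_genome,
    simulate_libraries,
    write_bed,
    write_fasta,
    write_truth_tsv,
)


def fig1c_hairpin_spec(seed: int) -> ToyGenomeSpec:
    """Hairpin-cluster fixture: 17 Lhp tags over a 1612-nt locus."""
    return ToyGenomeSpec(
        genome_length=8000,
        seed=seed,
        libraries=("zygote",),
        hairpin_loci=(
            HairpinLocus(arm=700, loop=212, position=3000, tag_count=17,
                         diverged_arm=True, anchor_tags=True),
        ),
    )


def fig2c_l1_spec(seed: int) -> ToyGenomeSpec:
    """L1 antisense-promoter fixture: 9 duplex tags plus decoys."""
    return ToyGenomeSpec(
        genome_length=12000,
        seed=seed,
        libraries=("zygote",),
        l1_locus=L1Locus(position=4000),
    )


def plce1_ic_spec(seed: int) -> ToyGenomeSpec:
    """Inverted-complement mRNA fixture: 217-nt arms, 2 in-arm tags,
    2 spacer decoys."""
    return ToyGenomeSpec(
        genome_length=3000,
        seed=seed,
        libraries=("zygote",),
        ic_mrnas=(
            ICmRNA(arm=217, spacer=100, position=1200, tag_count=2,
                   decoy_tag_count=2),
        ),
    )


def default_study_spec(seed: int) -> ToyGenomeSpec:
    """Three-stage study fixture with every feature class planted."""
    return ToyGenomeSpec(
        genome_length=120000,
        seed=seed,
        libraries=("sperm", "oocyte", "zygote"),
        l1_locus=L1Locus(position=5000),
        te_copies=(
            TECopy("L1", 800, 18000, tag_count=3),
            TECopy("LTR", 400, 28000, tag_count=4),
            TECopy("SINE", 300, 38000, tag_count=4),
            TECopy("ERV", 500, 48000, tag_count=4),
        ),
        mirna_loci=(GeneLocus(80, 58000, tag_count=4),),
        structural_loci=(GeneLocus(150, 68000, tag_count=3),),
        pirna_loci=(GeneLocus(200, 78000, tag_count=4),),
        ic_mrnas=(
            ICmRNA(arm=217, spacer=100, position=88000, tag_count=2,
                   decoy_tag_count=2),
        ),
        pirna_length_tag_sites=(
            TagSite(98000, 25), TagSite(98100, 27), TagSite(98200, 30),
        ),
        unknown_tag_sites=(
            TagSite(100000, 20), TagSite(100150, 22), TagSite(100300, 19),
        ),
        hairpin_loci=(
            HairpinLocus(arm=700, loop=212, position=108000, tag_count=17,
                         diverged_arm=True, anchor_tags=True),
        ),
    )


@dataclass
class MaterializedFixture:
    toy: ToyData
    workdir: Path
    config: Dict[str, object]


def materialize(
    toy: ToyData,
    workdir: str | Path,
    seed: int,
    sampling: str = "exact",
    background_fraction: float = 0.0,
    depths: Optional[Dict[str, int]] = None,
    adapter: str = DEFAULT_ADAPTER,
) -> MaterializedFixture:
    """Write every pipeline input file for a toy dataset and return a
    ready-to-run config."""
    workdir = Path(workdir)
    data = workdir / "data"
    data.mkdir(parents=True, exist_ok=True)
    chrom = toy.spec.chrom
    write_fasta([(chrom, toy.genome[chrom])], data / "genome.fasta")
    write_bed(toy.features, data / "features.bed")
    write_truth_tsv(toy.truth, data / "truth.tsv")
    libs = list(toy.spec.libraries)
    simulate_libraries(
        toy.genome, toy.truth, libs,
        depths or {l: 0 for l in libs},
        seed=seed, outdir=data, background_fraction=background_fraction,
        adapter=adapter, sampling=sampling,
    )
    config: Dict[str, object] = {
        "libraries": libs,
        "adapter": adapter,
        "seed": seed,
        "fastq_dir": str(data),
        "genome_fasta": str(data / "genome.fasta"),
    }
    if toy.mirna_refs:
        write_fasta(toy.mirna_refs, data / "mirna.fasta")
        config["mirna_fasta"] = str(data / "mirna.fasta")
    if toy.pirna_refs:
        write_fasta(toy.pirna_refs, data / "pirna.fasta")
        config["pirna_fasta"] = str(data / "pirna.fasta")
    if toy.structural_refs:
        write_fasta(toy.structural_refs, data / "structural.fasta")
        config["structural_fasta"] = str(data / "structural.fasta")
    if toy.repeat_library:
        write_fasta(toy.repeat_library, data / "repeats.fasta")
        config["repeat_fasta"] = str(data / "repeats.fasta")
    if toy.mrnas:
        write_fasta(sorted(toy.mrnas.items()), data / "mrna.fasta")
        config["mrna_fasta"] = str(data / "mrna.fasta")
    if toy.l1_bed:
        write_bed(toy.l1_bed, data / "l1.bed")
        write_fasta([(toy.l1_id, toy.l1_consensus)], data / "l1_consensus.fasta")
        config["l1_bed"] = str(data / "l1.bed")
        config["l1_consensus_fasta"] = str(data / "l1_consensus.fasta")
        l1 = toy.spec.l1_locus
        config["l1_target_start"] = l1.orf2[0]
        config["l1_target_end"] = l1.utr3[1]
        config["asl1_span"] = list(l1.asl1_span)
    if len(libs) < 2:
        config["diff_focal"] = libs[0]
        config["diff_comparators"] = []
    return MaterializedFixture(toy, workdir, config)


def run_fixture(
    spec: ToyGenomeSpec,
    workdir: str | Path,
    seed: int,
    outdir: Optional[str | Path] = None,
    **materialize_kwargs,
) -> pl.PipelineResult:
    """Build, materialize and run one fixture end to end."""
    toy = build_toy_genome(spec)
    fx = materialize(toy, workdir, seed, **materialize_kwargs)
    result = pl.run_pipeline(fx.config, outdir=outdir)
    result.toy = toy  # type: ignore[attr-defined]
    return result
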