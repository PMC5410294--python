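"""Toy genomes and simulated small-RNA libraries with planted truth.

The generator builds a random background genome and plants instances of
every feature class the pipeline must recognize: TE copies drawn from
family consensus sequences, long hairpin loci (exact or lightly diverged
inverted repeats), mRNAs carrying inverted-complement regions, an L1
locus with an antisense-promoter homology block upstream of its TSS, and
reference-backed miRNA / piRNA / structural-ncRNA genes. Every planted
tag is an exact substring of its source feature, so perfect-match
mappability is guaranteed by construction, and the truth table records
the intended final label of each tag.

Simulated libraries emulate three stages (sperm, oocyte, zygote) with a
bimodal background read-length profile peaking at 23 nt and 27-28 nt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from ._seq import comp_base, mutate_base, random_dna, revcomp, tag_id_for

log = logging.getLogger(__name__)

DEFAULT_LIBRARIES = ("sperm", "oocyte", "zygote")
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
TRUTH_LABELS = (
    "miRNA",
    "piRNA",
    "structural_ncRNA",
    "TE-siRNA",
    "Lhp-siRNA",
    "IC-siRNA",
    "L1-siRNA",
    "unknown",
)
_TAG_LENGTHS = (21, 22, 20, 23)  # cycled when planting candidate-length tags

# background read-length mixture: 0.5*N(23, 1) + 0.5*N(27.5, 0.8),
# discretized (round) and clipped to [18, 30]
LENGTH_MIX = ((23.0, 1.0, 0.5), (27.5, 0.8, 0.5))
LENGTH_MIN, LENGTH_MAX = 18, 30


# ------------------------------------------------------------ spec types

@dataclass(frozen=True)
class TECopy:
    family: str  # LTR | SINE | L1 | ERV
    length: int
    position: int
    tag_count: int = 3


@dataclass(frozen=True)
class HairpinLocus:
    arm: int
    loop: int
    position: int
    tag_count: int = 17
    diverged_arm: bool = False  # one mutation per 3'-arm tag window
    anchor_tags: bool = False  # two flank-straddling tags (label: unknown)


@dataclass(frozen=True)
class ICmRNA:
    arm: int
    spacer: int
    position: int
    tag_count: int = 2
    decoy_tag_count: int = 0  # planted in the spacer (label: unknown)
    length: Optional[int] = None  # total mRNA length; default 2*arm+spacer


@dataclass(frozen=True)
class L1Locus:
    position: int
    element_length: int = 3000
    orf1: Tuple[int, int] = (500, 1200)  # element-relative, half-open
    orf2: Tuple[int, int] = (1200, 2600)
    utr3: Tuple[int, int] = (2600, 3000)
    orf2_sub: Tuple[int, int] = (1600, 1965)  # homology target inside ORF2
    asp_block: Tuple[int, int] = (-1, -365)  # promoter coords of the block
    asl1_span: Tuple[int, int] = (93, -490)  # asL1 transcript span
    duplex_tag_count: int = 9
    duplex_antisense: int = 4  # of which antisense-strand tags
    decoy_tag_count: int = 3  # in ORF1, outside the duplex (label TE-siRNA)
    zygote_enriched: bool = True


@dataclass(frozen=True)
class GeneLocus:
    length: int
    position: int
    tag_count: int = 2


@dataclass(frozen=True)
class TagSite:
    position: int
    length: int


@dataclass(frozen=True)
class ToyGenomeSpec:
    genome_length: int
    seed: int
    chrom: str = "chr1"
    libraries: Tuple[str, ...] = DEFAULT_LIBRARIES
    te_copies: Tuple[TECopy, ...] = ()
    hairpin_loci: Tuple[HairpinLocus, ...] = ()
    ic_mrnas: Tuple[ICmRNA, ...] = ()
    l1_locus: Optional[L1Locus] = None
    mirna_loci: Tuple[GeneLocus, ...] = ()
    pirna_loci: Tuple[GeneLocus, ...] = ()
    structural_loci: Tuple[GeneLocus, ...] = ()
    pirna_length_tag_sites: Tuple[TagSite, ...] = ()  # piRNA by >24 nt rule
    unknown_tag_sites: Tuple[TagSite, ...] = ()


@dataclass
class ToyData:
    """Everything build_toy_genome produces."""

    spec: ToyGenomeSpec
    genome: Dict[str, str]
    features: List[Tuple[str, int, int, str, int, str]]  # BED6 rows
    truth: pd.DataFrame
    repeat_library: List[Tuple[str, str, str]]  # (id, family, seq)
    mirna_refs: List[Tuple[str, str]]
    pirna_refs: List[Tuple[str, str]]
    structural_refs: List[Tuple[str, str]]
    mrnas: Dict[str, str]
    l1_bed: List[Tuple[str, int, int, str, int, str]]
    l1_consensus: Optional[str] = None
    l1_id: str = "l1_full"


class FeatureOverlapError(ValueError):
    pass


# --------------------------------------------------------- construction

def _spread_starts(lo: int, hi: int, lengths: Sequence[int]) -> List[int]:
    """Evenly spread start positions for tags of ``lengths`` in [lo, hi)."""
    k = len(lengths)
    if k == 0:
        return []
    out = []
    for i, ln in enumerate(lengths):
        last = hi - ln
        if last < lo:
            raise ValueError("feature too small for requested tags")
        frac = i / (k - 1) if k > 1 else 0.0
        out.append(lo + int(round(frac * (last - lo))))
    return out


def _cycle_lengths(n: int, offset: int = 0) -> List[int]:
    return [_TAG_LENGTHS[(i + offset) % len(_TAG_LENGTHS)] for i in range(n)]


class _Builder:
    def __init__(self, spec: ToyGenomeSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.genome = list(random_dna(self.rng, spec.genome_length))
        self.intervals: List[Tuple[int, int, str]] = []
        self.features: List[Tuple[str, int, int, str, int, str]] = []
        self.truth_rows: List[dict] = []

    def claim(self, start: int, end: int, name: str, strand: str = "+",
              record: bool = True) -> None:
        if not (0 <= start < end <= self.spec.genome_length):
            raise ValueError(f"feature {name!r} interval {start}..{end} "
                             f"outside genome of {self.spec.genome_length} nt")
        for s, e, other in self.intervals:
            if start < e and s < end:
                raise FeatureOverlapError(
                    f"planted features overlap: {name!r} ({start}..{end}) "
                    f"and {other!r} ({s}..{e})"
                )
        self.intervals.append((start, end, name))
        if record:
            self.features.append((self.spec.chrom, start, end, name, 0, strand))

    def write(self, start: int, seq: str) -> None:
        self.genome[start : start + len(seq)] = list(seq)

    def abundances(self, enriched: bool = False) -> Dict[str, int]:
        out = {}
        for lib in self.spec.libraries:
            if enriched:
                out[lib] = (
                    int(self.rng.integers(250, 351))
                    if lib == "zygote"
                    else int(self.rng.integers(3, 9))
                )
            else:
                out[lib] = int(self.rng.integers(10, 61))
        return out

    def add_tag(self, seq: str, feature_id: str, label: str,
                family: str = "", enriched: bool = False) -> None:
        assert label in TRUTH_LABELS
        row = {
            "tag_id": tag_id_for(seq),
            "sequence": seq,
            "feature_id": feature_id,
            "label": label,
            "family": family,
        }
        row.update(self.abundances(enriched))
        self.truth_rows.append(row)


def build_toy_genome(spec: ToyGenomeSpec) -> ToyData:
    """Build the genome, feature annotations and truth table.

    Deterministic for a fixed seed. Raises :class:`FeatureOverlapError`
    naming both features if planted intervals overlap.
    """
    b = _Builder(spec)
    chrom = spec.chrom

    # --- TE families ------------------------------------------------
    repeat_library: List[Tuple[str, str, str]] = []
    consensus: Dict[str, str] = {}
    l1 = spec.l1_locus
    l1_element = None
    if l1 is not None:
        l1_element = random_dna(b.rng, l1.element_length)
        consensus["L1"] = l1_element
        repeat_library.append(("L1_consensus", "L1", l1_element))
    for fam in ("LTR", "SINE", "ERV"):
        lens = [c.length for c in spec.te_copies if c.family == fam]
        if lens:
            consensus[fam] = random_dna(b.rng, max(lens) + 100)
            repeat_library.append((f"{fam}_consensus", fam, consensus[fam]))

    for i, copy in enumerate(spec.te_copies):
        if copy.family not in consensus:
            if copy.family == "L1":
                raise ValueError("L1 TE copies require an l1_locus")
            raise ValueError(f"unknown TE family {copy.family!r}")
        name = f"te_{copy.family}_{i}"
        seq = consensus[copy.family][-copy.length :]  # 5'-truncated copy
        b.claim(copy.position, copy.position + copy.length, name)
        b.write(copy.position, seq)
        lengths = _cycle_lengths(copy.tag_count, offset=i)
        for start, ln in zip(_spread_starts(2, copy.length - 2, lengths), lengths):
            b.add_tag(seq[start : start + ln], name, "TE-siRNA", copy.family)

    # --- hairpin loci ----------------------------------------------
    for i, hp in enumerate(spec.hairpin_loci):
        name = f"hairpin_{i}"
        arm5 = random_dna(b.rng, hp.arm)
        loop = random_dna(b.rng, hp.loop)
        arm3 = revcomp(arm5)
        total = 2 * hp.arm + hp.loop
        margin = 5 if hp.arm >= 100 else 0
        n3 = hp.tag_count // 2 if hp.diverged_arm else 0
        n5 = hp.tag_count - n3
        lengths5 = _cycle_lengths(n5)
        starts5 = _spread_starts(margin, hp.arm - margin, lengths5)
        mut_positions: List[int] = []
        if n3:
            lengths3 = _cycle_lengths(n3, offset=1)
            starts3 = _spread_starts(margin, hp.arm - margin, lengths3)
            arm3_list = list(arm3)
            for s3, ln in zip(starts3, lengths3):
                center = s3 + ln // 2
                arm3_list[center] = mutate_base(b.rng, arm3_list[center])
                mut_positions.append(center)
            arm3 = "".join(arm3_list)
        hairpin_seq = arm5 + loop + arm3
        b.claim(hp.position, hp.position + total, name)
        b.write(hp.position, hairpin_seq)
        for s5, ln in zip(starts5, lengths5):
            b.add_tag(hairpin_seq[s5 : s5 + ln], name, "Lhp-siRNA")
        if n3:
            off = hp.arm + hp.loop
            for s3, ln in zip(starts3, lengths3):
                b.add_tag(hairpin_seq[off + s3 : off + s3 + ln], name, "Lhp-siRNA")
        if hp.anchor_tags:
            # anchor tags straddle the locus boundaries so the cluster
            # region covers the full hairpin; the flanks are poly-A (which
            # cannot pair with each other) so the folded arms never extend
            # past the planted stem and the anchors stay uncalled
            overhang, ln = 10, 22
            b.claim(hp.position - overhang, hp.position, f"{name}_flank5",
                    record=False)
            b.write(hp.position - overhang, "A" * overhang)
            b.claim(hp.position + total, hp.position + total + overhang,
                    f"{name}_flank3", record=False)
            b.write(hp.position + total, "A" * overhang)
            left = b_slice(b, hp.position - overhang, ln)
            right = b_slice(b, hp.position + total - (ln - overhang), ln)
            b.add_tag(left, name, "unknown")
            b.add_tag(right, name, "unknown")

    # --- inverted-complement mRNAs ----------------------------------
    mrnas: Dict[str, str] = {}
    for i, ic in enumerate(spec.ic_mrnas):
        name = f"mrna_{i}"
        S = random_dna(b.rng, ic.arm)
        spacer = random_dna(b.rng, ic.spacer)
        if ic.spacer >= 8:
            # boundary guards: the bases flanking the inverted repeat must
            # not extend the arm-arm complementarity past the planted arms
            sp = list(spacer)
            for k in range(3):
                while sp[k] == comp_base(sp[len(sp) - 1 - k]):
                    sp[k] = mutate_base(b.rng, sp[k])
            spacer = "".join(sp)
        core = S + spacer + revcomp(S)
        total = ic.length or len(core)
        if total < len(core):
            raise ValueError(f"{name}: total length shorter than arms+spacer")
        seq = core + random_dna(b.rng, total - len(core))
        b.claim(ic.position, ic.position + total, name)
        b.write(ic.position, seq)
        mrnas[name] = seq
        lengths = _cycle_lengths(ic.tag_count)
        margin = 2
        for k, ln in enumerate(lengths):
            if k % 2 == 0:  # 5' arm
                lo, hi = margin, ic.arm - margin
            else:  # 3' arm
                lo, hi = ic.arm + ic.spacer + margin, len(core) - margin
            start = _spread_starts(lo, hi, [ln] * (k // 2 + 1))[k // 2]
            b.add_tag(seq[start : start + ln], name, "IC-siRNA")
        if ic.decoy_tag_count:
            if ic.spacer < 26:
                raise ValueError(f"{name}: spacer too small for decoy tags")
            dl = _cycle_lengths(ic.decoy_tag_count, offset=2)
            for start, ln in zip(
                _spread_starts(ic.arm + 1, ic.arm + ic.spacer - 1, dl), dl
            ):
                b.add_tag(seq[start : start + ln], name, "unknown")

    # --- L1 locus with antisense-promoter block ---------------------
    l1_bed: List[Tuple[str, int, int, str, int, str]] = []
    l1_id = "l1_full"
    if l1 is not None:
        name = l1_id
        sub_lo, sub_hi = l1.orf2_sub
        sub_seq = l1_element[sub_lo:sub_hi]
        blk_len = abs(l1.asp_block[0] - l1.asp_block[1]) + 1
        if blk_len != sub_hi - sub_lo:
            raise ValueError("asp_block span must equal orf2_sub length")
        tss = l1.position
        b.claim(tss, tss + l1.element_length, name)
        b.write(tss, l1_element)
        blk_start = tss - blk_len  # promoter coords -blk_len .. -1
        b.claim(blk_start, tss, "l1_asp_block", record=True)
        b.write(blk_start, revcomp(sub_seq))
        # boundary guards: background just 5' of the block must not extend
        # the antisense homology past the planted 365 nt
        for k in range(3):
            gpos = blk_start - 1 - k
            if gpos < 0 or sub_hi + k >= l1.element_length:
                break
            bad = comp_base(l1_element[sub_hi + k])
            while b.genome[gpos] == bad:
                b.genome[gpos] = mutate_base(b.rng, b.genome[gpos])
        l1_bed.append((spec.chrom, tss, tss + l1.element_length, name, 0, "+"))

        n_anti = l1.duplex_antisense
        n_sense = l1.duplex_tag_count - n_anti
        lengths = _cycle_lengths(l1.duplex_tag_count)
        starts = _spread_starts(2, (sub_hi - sub_lo) - 2, lengths)
        for k, (s, ln) in enumerate(zip(starts, lengths)):
            frag = sub_seq[s : s + ln]
            seq = frag if k < n_sense else revcomp(frag)
            b.add_tag(seq, name, "L1-siRNA", "L1", enriched=l1.zygote_enriched)
        if l1.decoy_tag_count:
            dl = _cycle_lengths(l1.decoy_tag_count, offset=3)
            o1_lo, o1_hi = l1.orf1
            for s, ln in zip(_spread_starts(o1_lo + 2, o1_hi - 2, dl), dl):
                b.add_tag(l1_element[s : s + ln], name, "TE-siRNA", "L1")

    # --- reference-backed gene loci ---------------------------------
    mirna_refs: List[Tuple[str, str]] = []
    pirna_refs: List[Tuple[str, str]] = []
    structural_refs: List[Tuple[str, str]] = []
    for kind, loci, refs, label, lens_fn in (
        ("mirna", spec.mirna_loci, mirna_refs, "miRNA",
         lambda n: [(21, 22, 23, 24)[i % 4] for i in range(n)]),
        ("pirna", spec.pirna_loci, pirna_refs, "piRNA",
         lambda n: [(26, 27, 28)[i % 3] for i in range(n)]),
        ("structural", spec.structural_loci, structural_refs, "structural_ncRNA",
         lambda n: _cycle_lengths(n)),
    ):
        for i, locus in enumerate(loci):
            name = f"{kind}_{i}"
            gene = random_dna(b.rng, locus.length)
            b.claim(locus.position, locus.position + locus.length, name)
            b.write(locus.position, gene)
            refs.append((name, gene))
            lengths = lens_fn(locus.tag_count)
            for s, ln in zip(_spread_starts(0, locus.length, lengths), lengths):
                b.add_tag(gene[s : s + ln], name, label)

    # --- background-derived tags ------------------------------------
    for i, site in enumerate(spec.pirna_length_tag_sites):
        if not 25 <= site.length <= 30:
            raise ValueError("length-rule piRNA tags must be 25-30 nt")
        b.claim(site.position, site.position + site.length,
                f"pirna_len_{i}", record=False)
        b.add_tag(b_slice(b, site.position, site.length), f"pirna_len_{i}", "piRNA")
    for i, site in enumerate(spec.unknown_tag_sites):
        b.claim(site.position, site.position + site.length,
                f"unknown_{i}", record=False)
        b.add_tag(b_slice(b, site.position, site.length), f"unknown_{i}", "unknown")

    genome = {chrom: "".join(b.genome)}
    truth = pd.DataFrame(b.truth_rows)
    if not truth.empty:
        if truth["sequence"].duplicated().any():
            dup = truth[truth["sequence"].duplicated()].iloc[0]
            raise ValueError(f"planted tag collision at {dup['feature_id']}")
        for _, row in truth.iterrows():
            assert row["sequence"] in genome[chrom] or revcomp(row["sequence"]) in genome[chrom]
    log.info("toy genome: %d nt, %d features, %d planted tags",
             spec.genome_length, len(b.features), len(truth))
    return ToyData(
        spec=spec,
        genome=genome,
        features=b.features,
        truth=truth,
        repeat_library=repeat_library,
        mirna_refs=mirna_refs,
        pirna_refs=pirna_refs,
        structural_refs=structural_refs,
        mrnas=mrnas,
        l1_bed=l1_bed,
        l1_consensus=l1_element,
        l1_id=l1_id,
    )


def b_slice(b: _Builder, start: int, length: int) -> str:
    return "".join(b.genome[start : start + length])


# ----------------------------------------------------------- simulation

def background_length_pmf() -> Dict[int, float]:
    """Discretized, clipped pmf of the background length mixture."""
    pmf = {}
    for L in range(LENGTH_MIN, LENGTH_MAX + 1):
        lo = L - 0.5 if L > LENGTH_MIN else -np.inf
        hi = L + 0.5 if L < LENGTH_MAX else np.inf
        p = 0.0
        for mu, sd, w in LENGTH_MIX:
            p += w * (_stats.norm.cdf(hi, mu, sd) - _stats.norm.cdf(lo, mu, sd))
        pmf[L] = p
    return pmf


def sample_background_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    comp = rng.random(n) < LENGTH_MIX[0][2]
    vals = np.where(
        comp,
        rng.normal(LENGTH_MIX[0][0], LENGTH_MIX[0][1], n),
        rng.normal(LENGTH_MIX[1][0], LENGTH_MIX[1][1], n),
    )
    return np.clip(np.round(vals), LENGTH_MIN, LENGTH_MAX).astype(int)


def simulate_libraries(
    genome: Mapping[str, str],
    truth: pd.DataFrame,
    lib_names: Sequence[str],
    depths: Mapping[str, int],
    seed: int,
    outdir: str | Path,
    background_fraction: float = 0.1,
    adapter: str = DEFAULT_ADAPTER,
    sampling: str = "multinomial",
) -> Dict[str, Path]:
    """Write one FASTQ per library; returns library -> path.

    ``sampling="multinomial"`` draws planted reads by multinomial sampling
    from the intended abundances (depth minus the background share);
    ``sampling="exact"`` emits every planted tag exactly at its intended
    abundance (the deterministic noise-free regime used by the packaged
    study fixtures) and ignores ``depths``.
    """
    if sampling not in ("multinomial", "exact"):
        raise ValueError(f"unknown sampling mode {sampling!r}")
    if not 0 <= background_fraction < 1:
        raise ValueError("background fraction must be in [0, 1)")
    for lib in truth.columns:
        pass
    missing = [l for l in lib_names if not truth.empty and l not in truth.columns]
    if missing:
        raise ValueError(f"truth table lacks abundances for libraries {missing}")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms = sorted(genome)
    chrom_seqs = [genome[c] for c in chroms]
    paths = {}
    for lib in lib_names:
        if sampling == "multinomial":
            depth = int(depths[lib])
            if depth < 0:
                raise ValueError("library depth must be non-negative")
            n_bg = int(round(background_fraction * depth))
            n_planted = depth - n_bg
        else:
            n_planted = 0 if truth.empty else int(truth[lib].sum())
            n_bg = (
                int(round(background_fraction * n_planted / (1 - background_fraction)))
                if background_fraction
                else 0
            )
        reads: List[str] = []
        if not truth.empty and n_planted > 0:
            weights = truth[lib].to_numpy(float)
            if sampling == "multinomial":
                if weights.sum() <= 0:
                    raise ValueError(f"no planted abundance in library {lib!r}")
                counts = rng.multinomial(n_planted, weights / weights.sum())
            else:
                counts = truth[lib].to_numpy(int)
            for seq, c in zip(truth["sequence"], counts):
                reads.extend([seq] * int(c))
        if n_bg:
            lengths = sample_background_lengths(rng, n_bg)
            for ln in lengths:
                for _ in range(50):  # rejection-sample around Ns
                    ci = int(rng.integers(0, len(chroms)))
                    seq = chrom_seqs[ci]
                    pos = int(rng.integers(0, max(1, len(seq) - ln)))
                    frag = seq[pos : pos + int(ln)]
                    if "N" not in frag and len(frag) == ln:
                        break
                else:
                    raise RuntimeError("could not sample an N-free background read")
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                reads.append(frag)
        path = outdir / f"{lib}.fastq"
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                full = seq + adapter
                fh.write(f"@{lib}_{i}\n{full}\n+\n{'I' * len(full)}\n")
        paths[lib] = path
        log.info("library %s: %d planted + %d background reads", lib,
                 len(reads) - n_bg, n_bg)
    return paths


# ------------------------------------------------------------- outputs

def write_fasta(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        for item in records:
            if len(item) == 3:  # repeat library with family tag
                rec_id, family, seq = item
                fh.write(f">{rec_id} family={family}\n{seq}\n")
            else:
                rec_id, seq = item
                fh.write(f">{rec_id}\n{seq}\n")


def write_bed(rows, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- evaluation

def predicted_truth_label(final_ann, assigned_l1: set) -> str:
    """Collapse a pipeline FinalAnnotation into the truth label space."""
    if final_ann.label == "endo_siRNA":
        if final_ann.subclass == "TE":
            return "L1-siRNA" if final_ann.tag_id in assigned_l1 else "TE-siRNA"
        return {"Lhp": "Lhp-siRNA", "IC": "IC-siRNA"}[final_ann.subclass]
    return final_ann.label


def score_against_truth(
    truth: pd.DataFrame,
    final_annotations: Mapping,
    assigned_l1: set,
) -> pd.DataFrame:
    """Per-class precision/recall of final labels against planted truth.

    Only planted tags are scored (in a noise-free run they are the only
    survivors); a planted tag missing from the final annotations counts
    as a recall failure for its class.
    """
    rows = []
    pred = {
        tid: predicted_truth_label(ann, assigned_l1)
        for tid, ann in final_annotations.items()
    }
    for label in TRUTH_LABELS:
        want = set(truth.loc[truth["label"] == label, "tag_id"])
        got = {tid for tid, p in pred.items() if p == label}
        tp = len(want & got)
        rows.append(
            {
                "label": label,
                "planted": len(want),
                "called": len(got),
                "tp": tp,
                "precision": tp / len(got) if got else 1.0,
                "recall": tp / len(want) if want else 1.0,
            }
        )
    return pd.DataFrame(rows).set_index("label")
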