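# Methods

## Scope and model

The package decides, for every collapsed small-RNA tag, which precursor
structure best explains it. The decision cascade is:

1. **Filtering.** Reads containing N are removed; the 3′ adapter is
   trimmed (leftmost occurrence of an adapter prefix, minimum overlap
   6 nt, no mismatches — the trimmer parameters of the original
   processing are unknown, so the simplest deterministic rule is used);
   trimmed reads outside 18–30 nt are removed; identical sequences are
   collapsed into tags with per-library counts; tags with total count
   ≤ 2 are removed. The count floor is applied to the total across
   libraries by default (`count_filter_scope: total`); a per-library
   variant is available, since libraries sequenced separately could be
   filtered either way.
2. **Mapping.** Perfect-match only. A multi-mapping tag gets exactly one
   hit: the minimum under (chrom lexicographic, start ascending, `+`
   before `-`). A `-k1`-style aligner also reports one hit but chooses
   it unpredictably; the total order makes runs reproducible. `N` in the
   genome matches nothing.
3. **Tier annotation**, first match wins: structural ncRNA (homology),
   miRNA (21–24 nt and homology), piRNA (homology OR 25–30 nt),
   endo-siRNA candidate (18–24 nt), unknown. "Homology" is an exact
   substring match against a reference or its reverse complement
   (a mismatch tolerance is exposed but defaults to 0). The tier
   precedence when a tag matches several reference kinds is a package
   decision; it is tested explicitly. Structural-ncRNA tags are set
   aside after this step and do not appear in the four-class summary.
4. **Subclassification** of candidates: TE (perfect match, either
   strand, to a family-tagged repeat record; first record wins ties),
   Lhp (see below), IC (see below). Priority TE > Lhp > IC when several
   rules fire — a repeat match is the most specific sequence-level
   evidence. Candidates with no call revert to unknown.

## Clusters and hairpins

Clusters are maximal greedy left-to-right runs of mapped hits: a run is
extended while the span from the first hit start to the candidate hit
end stays strictly below 10 kb, and is emitted when it contains at
least 16 distinct tag sequences ("more than 15"). Cluster membership
counts any mapped small RNA by default (`cluster_scope: any`),
switchable to candidates only. Greedy placement is a choice; tests
compare it against exhaustive maximal-window enumeration on layouts
with well-separated clusters, where the two coincide.

Cluster regions are folded by base-pair maximization (Nussinov) with
Watson–Crick plus G·U wobble pairs, minimum loop 3, nested pairs only.
The hairpin question the pipeline asks — does this region fold back on
itself with two long arms — does not need free energies, and pair
counting keeps the folder dependency-free and exactly testable against
brute-force enumeration (n ≤ 12). An adapter point for a thermodynamic
folder would slot in at `fold_region`. The traceback prefers pairing
the outermost bases whenever that is optimal, which keeps long stems
contiguous. Arms are the two strands of the longest contiguous helix
extended over directly stacked helices with interior gaps ≤ 4 nt on
both strands.

A region qualifies as a long hairpin iff its paired fraction
(2·pairs / length) is ≥ 0.5 (`lhp.min_paired_fraction`) and both arms
are ≥ 20 nt (`lhp.min_arm`); "long hairpin" has no published
operational definition, so both thresholds are config keys. Note that
under pure pair maximization, random sequence attains high paired
fractions, so the arm-length requirement and — decisively — the cluster
threshold (≥ 16 distinct tags) carry most of the specificity. Lhp calls
go to candidate tags whose hit lies entirely within an arm.

## Inverted-complement regions

Each mRNA is locally aligned against its own reverse complement
(Smith–Waterman, affine gaps; +2 / −3 match/mismatch, gap open −5,
extend −2 per base — blastn-like values, all exposed in config).
Alignments of length ≥ 30 at identity ≥ 0.8 become IC regions.

Two implementation points matter. First, an mRNA of the form
S + spacer + revcomp(S) aligned against its own reverse complement has
a spurious full-length self-alignment (both arms match themselves,
bridging the spacer) that outscores the true inverted repeat; the DP is
therefore restricted to the half matrix where the target position is
strictly upstream of the mirrored query position, which removes the
bridge and all mirror duplicates while provably keeping every true
arm1-before-arm2 repeat. Second, suboptimal alignments are needed
(several IC regions per mRNA), so the aligner iterates
Waterman–Eggert-style: extract the best alignment, mask its target and
query positions, re-align until the score floor. This is why the
aligner is written here (with numba) rather than taken from a library
aligner, which only reports co-optimal alignments of the single best
score. IC calls go to candidate tags whose mRNA-space hit lies entirely
within an arm.

## Zygote-enrichment screen

Counts are normalized as CPM with a 0.5 pseudocount on count and total,
keeping folds finite; the test is a two-sided Fisher exact test on
[[count, total − count], [count', total' − count']]. Both the test and
the normalization are package choices (the screen's original statistic
is unstated); both are config keys. A tag is selected iff, against
*every* comparator library, fold > 2 and p < 0.01 — strict
inequalities. No multiple-testing correction by default (the screen is
a raw-threshold filter); `bh_correct` enables Benjamini–Hochberg.
Library totals are read sums over mapped surviving tags.

## The asL1 duplex

Promoter coordinates use +1 for the first transcribed base and negative
values upstream, with no position 0; internally coordinate c maps to
the integer line as c−1 (c > 0) or c (c < 0), making interval
arithmetic ordinary and the conversion a bijection. For every annotated
L1 copy the 3000-nt upstream flank is extracted strand-aware (truncated
flanks are flagged), then locally aligned against the reverse
complement of the ORF2 + 3′UTR transcript region; blocks of length
≥ 50 at identity ≥ 0.8 are reported with their upstream interval in
promoter coordinates. The dsRNA duplex is the integer-line intersection
of a block's upstream interval with the asL1 span (+93..−490 by
default, taken as an input — transcript-end inference is out of scope);
the block with the longest intersection is the reported duplex. An
empty intersection yields a zero-length duplex flagged inactive.
Candidate tags are re-mapped onto the L1 consensus and assigned to the
duplex when their hit lies entirely within its sense-side interval,
labeled sense/antisense by hit strand. "Ends at −490" is treated as
inclusive.

## Synthetic data

`endosirna.synth` builds toy genomes with uniform random background and
planted features, each an exact construction: hairpin loci are exact
inverted repeats (arm + loop + revcomp(arm)); IC mRNAs are
S + spacer + revcomp(S); the L1 locus carries, immediately upstream of
its TSS, the exact reverse complement of a 365-nt ORF2 sub-interval.
Planted tags are exact substrings of their feature, so perfect-match
mappability is guaranteed. Truth tables record each tag's intended
label and per-library abundance.

Two deliberate deviations from the idealized constructions:

* The packaged hairpin-cluster fixture uses a lightly *diverged* 3′ arm
  (one substitution at the center of each 3′-arm tag window). With a
  mathematically exact inverted repeat, every 3′-arm tag also occurs
  (reverse-complemented) in the 5′ arm, and the single-hit mapper's
  total order would place all reads in the 5′ arm — no read could ever
  map across the full locus. Real hairpin loci are diverged, which is
  exactly why reads map to both arms of real clusters. Each 3′-arm tag
  covers one divergent position and therefore maps uniquely.
* Feature boundaries carry small guards (poly-A flanks around hairpins,
  non-complementary bases at spacer/block junctions) so that local
  alignments and folded arms terminate exactly at the planted
  boundaries instead of extending by chance matches; without them the
  reported arm/block lengths would wobble by a few nt across seeds.

Simulated libraries append a configurable 3′ adapter, use constant
quality `I` (quality is never consumed), and draw background reads from
random genome positions with lengths from the discretized, clipped
mixture 0.5·N(23, 1) + 0.5·N(27.5, 0.8) on [18, 30] — the bimodal
profile of real gamete/zygote libraries (miRNA/endo-siRNA peak at
23 nt, piRNA peak at 27–28 nt) without claiming exact proportions.
Planted reads are drawn multinomially from intended abundances
(`sampling="multinomial"`), or emitted exactly at their intended
abundance (`sampling="exact"`), the regime the noise-free packaged
fixtures use so that planted-truth recovery is deterministic for every
seed. Library depths for the toy study are the exact-abundance sums
(roughly 2–5 k reads per library); these sizes exercise every code path
while keeping the full study run in seconds.

What the generator does *not* emulate: sequencing errors, UMIs,
ping-pong piRNA signatures, realistic repeat-family divergence, or
chromosome-scale genomes. Passing the planted-recovery tests therefore
shows the decision cascade is implemented correctly, not that its
thresholds are optimal on real libraries.

## Numerical and degenerate-input notes

* Percentages in the class summary are integers, rounded half away from
  zero (6.63 % → 7). Empty inputs give zero rows without division.
* `fold_region` accepts any sequence of length ≥ 5; the pipeline folds
  only cluster regions of 40–20 000 nt and logs a skip otherwise.
* Fisher p-values agree with exhaustive hypergeometric summation to
  1e-10 for totals ≤ 2000 (tested); CPM antisymmetry
  fold(a,b)·fold(b,a) = 1 holds exactly.
* The depth-0 library is a valid empty FASTQ; an adapter of "" disables
  trimming; a read equal to the adapter trims to "" and is removed by
  the length filter.
* All stages are deterministic given the config seed; two identical
  runs produce byte-identical output trees (tested).

## Known limitations

* Homology is exact substring matching by default; a single mismatch
  tolerance is available but slow for large reference sets.
* The exact-match index is a k-mer seed table over plain Python
  strings, sized for toy genomes (≤ a few Mb), not for a real
  chromosome-scale run, which is out of scope.
* Pair-maximization folding over-pairs random sequence; paired-fraction
  thresholds are not transferable to a thermodynamic folder without
  recalibration.
* Single libraries per stage: the screen has no replicate-aware
  dispersion model by design.
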