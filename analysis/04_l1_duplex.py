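#!/usr/bin/env python
"""Model the L1 antisense-promoter dsRNA: extract 3000-nt upstream flanks
of annotated L1 copies, align them antisense against the ORF2 + 3'UTR
transcript region, intersect the best homology block with the asL1
transcript span (+93..-490), and assign small-RNA tags to the resulting
duplex with sense/antisense labels.

Run analysis/01_simulate.py first. Outputs under results/l1/.
"""

import sys
from pathlib import Path

import yaml

from endosirna.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data"
    with open(data / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    out = ROOT / "results" / "l1"
    result = run_pipeline(cfg, outdir=out)

    print(f"extracted {len(result.flanks)} upstream flanks "
          f"({sum(f.truncated for f in result.flanks)} truncated)")
    for b in result.blocks:
        print(f"  block {b.l1_id}: upstream {b.upstream_from}..{b.upstream_to} "
              f"~ transcript {b.target_start}..{b.target_end} "
              f"identity={b.identity:.3f}")
    d = result.duplex
    if d is not None:
        print(f"duplex: asL1 {d.asl1_span[0]:+d}..{d.asl1_span[1]:+d}, "
              f"length {d.length} nt, sense interval {d.sense_interval}")
        strands = [s for _, s in result.l1_assigned]
        print(f"assigned L1-siRNAs: {len(result.l1_assigned)} "
              f"({strands.count('sense')} sense, "
              f"{strands.count('antisense')} antisense)")
    else:
        print("no active duplex found")


if __name__ == "__main__":
    sys.exit(main())
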