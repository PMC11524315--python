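#!/usr/bin/env python
"""Detect duplicated gene pairs (strict 80/80 rule) and gene hotspots.

Every same-family gene pair is aligned at the CDS level; pairs whose
alignment covers more than 80% of the longer gene at more than 80%
identity are duplicates, flagged tandem when they sit within 100 kb on
one chromosome. Hotspots are maximal regions of five or more catalogue
genes spanning less than 5 Mb.
"""

import argparse
from pathlib import Path

from monolignol.pipeline import PipelineConfig, run_stage

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "analysis")
    args = parser.parse_args()
    cfg = PipelineConfig(study_dir=args.study, out_dir=args.out, seed=args.seed)
    dup = run_stage("duplicates", cfg)
    print(f"{dup['n_pairs']} duplicate pairs ({dup['n_tandem']} tandem)")
    hot = run_stage("hotspots", cfg)
    print(f"{hot['n_hotspots']} hotspots:")
    for chrom, start, end in hot["hotspots"]:
        print(f"  {chrom}:{start}-{end} ({(end - start + 1) / 1e6:.2f} Mb)")


if __name__ == "__main__":
    main()
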