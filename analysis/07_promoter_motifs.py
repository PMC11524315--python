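#!/usr/bin/env python
"""Scan 2000-bp promoters for cis-element motifs and tabulate frequencies.

Exact IUPAC matching on both strands over the motif vocabulary; hit
counts are aggregated per gene, per family, and for the xylem-specific
gene subset.
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
    info = run_stage("motifs", cfg)
    print(
        f"{info['n_hits']} motif hits over {info['n_motifs']} motifs; "
        f"xylem subset: {info.get('n_xylem_genes', 0)} genes"
    )
    print(f"matrices written under {args.out}")


if __name__ == "__main__":
    main()
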