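#!/usr/bin/env python
"""Normalize counts to FPKM, filter, and call tall-vs-short DEGs.

Genes with FPKM > 1 in at least one replicate are tested; a gene is a
DEG when the tall/short fold change is at least 2 and the BH-adjusted
p-value is below 0.05.
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
    info = run_stage("degs", cfg)
    print(
        f"{info['n_expressed']}/{info['n_genes']} genes expressed; "
        f"{info['n_deg']} DEGs ({info['deg_fraction']} of tested)"
    )
    print(
        f"  {info['n_up_in_short']} up in short, "
        f"{info['n_up_in_tall']} up in tall genotypes"
    )


if __name__ == "__main__":
    main()
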