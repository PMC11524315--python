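#!/usr/bin/env python
"""Build per-family NJ trees and classify each family's evolution.

Poisson-corrected distances under pairwise deletion feed neighbor
joining with column-bootstrap support; each family is then labelled
Ia (monocots split off), Ib (monocots, herbaceous dicots and woody taxa
each monophyletic) or II (groups interleaved — an expanded family).
"""

import argparse
from pathlib import Path

from monolignol.pipeline import PipelineConfig, run_stage

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--bootstrap-reps", type=int, default=1000)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "analysis")
    args = parser.parse_args()
    cfg = PipelineConfig(
        study_dir=args.study, out_dir=args.out, seed=args.seed,
        bootstrap_reps=args.bootstrap_reps,
    )
    info = run_stage("trees", cfg)
    for family, cls in info["classes"].items():
        print(f"  {family:8s} class {cls}")


if __name__ == "__main__":
    main()
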