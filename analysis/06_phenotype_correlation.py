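#!/usr/bin/env python
"""Correlate tree height with lignin content.

Reports the Pearson correlation across genotype means for the synthetic
study, and recomputes the same statistic from the bundled published
genotype means (which give r = -0.62).
"""

import argparse
from pathlib import Path

from monolignol.phenotype import height_lignin_correlation, load_reference_phenotypes
from monolignol.pipeline import PipelineConfig, run_stage

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "analysis")
    args = parser.parse_args()
    cfg = PipelineConfig(study_dir=args.study, out_dir=args.out, seed=args.seed)
    info = run_stage("phenotype", cfg)
    print(f"synthetic study: r = {info['r']:.3f} (p = {info['p_value']:.3f}, n = {info['n']})")
    ref = height_lignin_correlation(load_reference_phenotypes())
    print(f"published genotype means: r = {ref.r:.2f} (p = {ref.p_value:.3f}, n = {ref.n})")


if __name__ == "__main__":
    main()
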