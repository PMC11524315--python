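"""Lignin content from the acetylation assay and its relation to height.

The assay converts an OD280 absorbance difference ΔA and a dry weight W
(grams) into lignin content as 2.184 x ΔA / W (mg per g dry weight). The
height-lignin association is the sample Pearson correlation across
genotype means (default) or across individual replicates, with a
two-sided p-value from the exact t reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import stats

from .models import LIGNIN_ASSAY_COEF, PhenotypeRecord


def load_reference_phenotypes() -> list[PhenotypeRecord]:
    """Bundled published genotype means: height (cm) and lignin (mg/g)
    for the two parents and two F1 progeny."""
    import pandas as pd

    src = resources.files("monolignol.data") / "reference_phenotypes.tsv"
    df = pd.read_csv(src.open(), sep="\t")
    return [
        PhenotypeRecord(
            genotype=row.genotype,
            height_cm=float(row.height_cm),
            lignin_mg_per_g=float(row.lignin_mg_per_g),
        )
        for row in df.itertuples()
    ]


def lignin_content(delta_A: float, dry_weight_g: float) -> float:
    """Lignin content (mg/g) = 2.184 x ΔA / W."""
    if dry_weight_g <= 0:
        raise ValueError("dry weight must be positive")
    if delta_A < 0:
        raise ValueError("delta_A must be >= 0")
    return LIGNIN_ASSAY_COEF * delta_A / dry_weight_g


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-based p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.isclose(x.var(), 0) or np.isclose(y.var(), 0):
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    p_value: float
    n: int
    mode: str  # genotype_means | replicates


def height_lignin_correlation(
    records: list[PhenotypeRecord], mode: str = "genotype_means"
) -> CorrelationReport:
    """Correlate height with lignin content across phenotype records.

    With ``mode="genotype_means"`` records are averaged per genotype
    first (one point per genotype, the default); ``"replicates"`` uses
    every record as its own point.
    """
    if mode not in ("genotype_means", "replicates"):
        raise ValueError("mode must be genotype_means or replicates")
    if mode == "genotype_means":
        by_geno: dict[str, list[PhenotypeRecord]] = {}
        for rec in records:
            by_geno.setdefault(rec.genotype, []).append(rec)
        heights = [np.mean([r.height_cm for r in v]) for v in by_geno.values()]
        lignins = [np.mean([r.lignin for r in v]) for v in by_geno.values()]
    else:
        heights = [r.height_cm for r in records]
        lignins = [r.lignin for r in records]
    r, p = pearson_with_p(heights, lignins)
    return CorrelationReport(r=r, p_value=p, n=len(heights), mode=mode)
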