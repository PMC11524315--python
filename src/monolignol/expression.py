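"""FPKM normalization, expression filtering and DEG calling.

The decision rule for a differentially expressed gene between the tall
and short height classes is the conventional two-criterion one: at least
a two-fold difference in mean FPKM (|log2 fold change| >= 1, computed on
(mean + 1)-shifted values so all-zero genes are defined) and a
Benjamini-Hochberg adjusted p-value below 0.05. The per-gene p-value
comes from a two-sided Welch t-test on log2(FPKM + 1); the test is a
configurable hook, the decision rule is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import SampleInfo

MIN_FPKM = 1.0
FC_THRESHOLD = 2.0
FDR = 0.05


@dataclass
class ExpressionMatrix:
    """FPKM by gene x sample, with gene lengths and sample metadata."""

    fpkm: pd.DataFrame  # genes x samples
    gene_lengths: pd.Series  # bp, aligned to fpkm.index
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        if list(self.fpkm.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("fpkm columns do not match samples")
        if not self.fpkm.index.equals(self.gene_lengths.index):
            raise ValueError("gene_lengths index does not match fpkm")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM must be nonnegative")


@dataclass(frozen=True)
class DEGResult:
    gene_id: str
    mean_fpkm_tall: float
    mean_fpkm_short: float
    log2fc: float
    p_value: float
    q_value: float
    is_deg: bool
    direction: str  # up_in_tall | up_in_short


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    samples: list[SampleInfo],
) -> ExpressionMatrix:
    """fpkm[g, s] = counts[g, s] * 1e9 / (length[g] * total_counts[s])."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise ValueError(f"missing gene lengths for {missing}")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals[totals <= 0].index)
        raise ValueError(f"zero library size for samples {empty}")
    fpkm = counts * 1e9
    fpkm = fpkm.div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(fpkm=fpkm, gene_lengths=lengths, samples=samples)


def filter_expressed(matrix: ExpressionMatrix, min_fpkm: float = MIN_FPKM) -> list[str]:
    """Genes with FPKM strictly above ``min_fpkm`` in >= 1 sample."""
    keep = matrix.fpkm.max(axis=1) > min_fpkm
    return list(matrix.fpkm.index[keep])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_log_t(tall: np.ndarray, short: np.ndarray) -> float:
    """Two-sided Welch t on log2(FPKM + 1); degenerate variance -> p = 1."""
    a, b = np.log2(tall + 1.0), np.log2(short + 1.0)
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def call_degs(
    matrix: ExpressionMatrix,
    fc_threshold: float = FC_THRESHOLD,
    fdr: float = FDR,
    genes: Sequence[str] | None = None,
    test: Callable[[np.ndarray, np.ndarray], float] = welch_log_t,
) -> list[DEGResult]:
    """Call DEGs between the tall and short sample groups.

    ``genes`` restricts testing to a pre-filtered subset (the expressed
    genes); both groups need at least two samples.
    """
    tall_ids = [s.sample_id for s in matrix.samples if s.height_class == "tall"]
    short_ids = [s.sample_id for s in matrix.samples if s.height_class == "short"]
    if len(tall_ids) < 2 or len(short_ids) < 2:
        raise ValueError("need >= 2 samples per height class")
    fpkm = matrix.fpkm if genes is None else matrix.fpkm.loc[list(genes)]
    lfc_cut = np.log2(fc_threshold)

    p_values = []
    rows = []
    for gene_id, row in fpkm.iterrows():
        tall = row[tall_ids].to_numpy(dtype=float)
        short = row[short_ids].to_numpy(dtype=float)
        mean_tall, mean_short = tall.mean(), short.mean()
        log2fc = float(np.log2((mean_tall + 1.0) / (mean_short + 1.0)))
        p = test(tall, short)
        p_values.append(p)
        rows.append((gene_id, mean_tall, mean_short, log2fc, p))

    q_values = bh_adjust(p_values) if p_values else np.array([])
    results = []
    for (gene_id, mt, ms, lfc, p), q in zip(rows, q_values):
        is_deg = abs(lfc) >= lfc_cut and q < fdr
        results.append(
            DEGResult(
                gene_id=gene_id,
                mean_fpkm_tall=float(mt),
                mean_fpkm_short=float(ms),
                log2fc=lfc,
                p_value=float(p),
                q_value=float(q),
                is_deg=bool(is_deg),
                direction="up_in_tall" if lfc > 0 else "up_in_short",
            )
        )
    return results


def expression_heat_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2(FPKM + 1) per gene and sample, for heatmap rendering."""
    return np.log2(matrix.fpkm + 1.0)


def deg_fraction_text(n_deg: int, n_tested: int) -> str:
    """Format a DEG tally, e.g. 23 of 117 -> '19.66%'."""
    return f"{100.0 * n_deg / n_tested:.2f}%"


def degs_to_frame(results: list[DEGResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.gene_id, r.mean_fpkm_tall, r.mean_fpkm_short, r.log2fc,
                r.p_value, r.q_value, r.is_deg, r.direction,
            )
            for r in results
        ],
        columns=[
            "gene_id", "mean_fpkm_tall", "mean_fpkm_short", "log2fc",
            "p_value", "q_value", "is_deg", "direction",
        ],
    )
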