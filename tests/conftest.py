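"""Shared fixtures and independent oracles for the test suite.

The oracles here (brute-force Smith-Waterman, subinterval hotspot
enumeration, naive motif scan, step-up FDR) are deliberately separate
implementations against which the package's faster paths are checked.
"""

from __future__ import annotations

import numpy as np
import pytest

from monolignol.models import SeqEntry
from monolignol.pipeline import PipelineConfig, run_all
from monolignol.synthetic import DuplicateSpec, HotspotSpec, StudyConfig

# ---------------------------------------------------------------------------
# oracles


def sw_score_oracle(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Textbook Smith-Waterman with linear gaps; returns (score, identity,
    coverage_of_longer) of the best local alignment via traceback."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    score = H.max()
    if score == 0:
        return 0.0, 0.0, 0.0
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    end_i, end_j = i, j
    matches = cols = 0
    while H[i, j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if i > 0 and j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + s):
            matches += a[i - 1] == b[j - 1]
            cols += 1
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(H[i, j], H[i - 1, j] + gap):
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    span_longer = (end_i - i) if n >= m else (end_j - j)
    return float(score), matches / cols, span_longer / max(n, m)


def hotspot_oracle(positions, min_genes=5, window_bp=5_000_000):
    """All maximal qualifying subintervals over (start, end) tuples sorted
    by start; returns list of (i, j) index runs."""
    pos = sorted(positions)
    n = len(pos)
    runs = []
    for i in range(n):
        for j in range(i + min_genes - 1, n):
            span = max(e for _s, e in pos[i : j + 1]) - pos[i][0] + 1
            if span < window_bp:
                runs.append((i, j))
    return [
        (i, j)
        for (i, j) in runs
        if not any(p <= i and j <= q and (p, q) != (i, j) for (p, q) in runs)
    ]


def naive_scan_oracle(seq: str, motif: str):
    """Position-by-position IUPAC scan of both strands."""
    from monolignol.motifs import IUPAC, revcomp

    seq = seq.upper()
    hits = []
    for pattern, strand in ((motif.upper(), "+"), (revcomp(motif), "-")):
        for off in range(len(seq) - len(pattern) + 1):
            window = seq[off : off + len(pattern)]
            if all(c in "ACGT" and c in IUPAC[p] for c, p in zip(window, pattern)):
                hits.append((off, strand))
    return sorted(hits)


def bh_oracle(p):
    """Benjamini-Hochberg step-up from its definition: sort ascending,
    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1, order restored."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    best = np.inf
    for rank in range(m - 1, -1, -1):
        best = min(best, p[order[rank]] * m / (rank + 1))
        q_sorted[rank] = min(best, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# fixtures


def small_study_config() -> StudyConfig:
    """Desk-scale study used by pipeline-level tests."""
    return StudyConfig(
        genes_per_family=4,
        n_unplaced=5,
        cds_len=600,
        hotspots=(
            HotspotSpec("chrA01", 6, 3_000_000),
            HotspotSpec("chrB16", 5, 2_500_000),
        ),
        duplicates=(
            DuplicateSpec(0.95, 1.0, tandem=True),
            DuplicateSpec(0.85, 1.0, tandem=False),
        ),
        n_deg_up_short=5,
        n_deg_up_tall=2,
        msa_columns=200,
    )


@pytest.fixture(scope="session")
def small_run_pair(tmp_path_factory):
    """The same small synthetic end-to-end run executed twice."""
    outs = []
    for tag in ("one", "two"):
        base = tmp_path_factory.mktemp(f"run_{tag}")
        cfg = PipelineConfig(
            study_dir=base / "study",
            out_dir=base / "out",
            seed=7,
            synthetic=True,
            bootstrap_reps=50,
            study=small_study_config(),
        )
        summary = run_all(cfg)
        outs.append((base, summary))
    return outs


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def dna_entry(name: str, seq: str) -> SeqEntry:
    return SeqEntry(id=name, residues=seq, alphabet="dna")
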