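"""Local pairwise alignment with identity and coverage statistics.

This is the search primitive behind family assignment and duplicate
detection. Alignment is optimal Smith-Waterman-style local alignment
(via Bio.Align.PairwiseAligner); from the best alignment we report

* ``identity``       — matching columns / aligned columns (gap columns
  inside the local alignment count as columns),
* ``coverage_longer`` — the extent of the aligned region within the longer
  sequence divided by the longer sequence's full length.

These two fractions feed the strict >0.80 / >0.80 duplication rule.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .models import SeqEntry


@dataclass(frozen=True)
class Scoring:
    """Simple scoring for DNA: match/mismatch plus a linear gap penalty."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    span_a: tuple[int, int]  # 0-based half-open within a
    span_b: tuple[int, int]
    identity: float
    coverage_longer: float


def _make_aligner(alphabet: str, scoring: Scoring | None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    else:
        s = scoring or Scoring()
        aligner.match_score = s.match
        aligner.mismatch_score = s.mismatch
        aligner.open_gap_score = s.gap
        aligner.extend_gap_score = s.gap
    return aligner


def align_local(
    a: SeqEntry, b: SeqEntry, scoring: Scoring | None = None
) -> LocalAlignment:
    """Optimal local alignment of two sequences of the same alphabet."""
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    if a.alphabet != b.alphabet:
        raise ValueError(
            f"alphabet mismatch: {a.id}={a.alphabet}, {b.id}={b.alphabet}"
        )
    aligner = _make_aligner(a.alphabet, scoring)
    sa, sb = a.residues.upper(), b.residues.upper()
    alignments = aligner.align(sa, sb)
    if alignments.score <= 0:  # no positive-scoring local segment at all
        return LocalAlignment(
            score=0.0, span_a=(0, 0), span_b=(0, 0),
            identity=0.0, coverage_longer=0.0,
        )
    alignment = alignments[0]

    blocks_a, blocks_b = alignment.aligned
    matches = 0
    aligned_cols = 0
    prev_a = prev_b = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            aligned_cols += (a0 - prev_a) + (b0 - prev_b)  # internal gap columns
        for i, j in zip(range(a0, a1), range(b0, b1)):
            matches += sa[i] == sb[j]
        aligned_cols += a1 - a0
        prev_a, prev_b = a1, b1

    start_a, end_a = int(blocks_a[0][0]), int(blocks_a[-1][1])
    start_b, end_b = int(blocks_b[0][0]), int(blocks_b[-1][1])
    if len(sa) >= len(sb):
        cov = (end_a - start_a) / len(sa)
    else:
        cov = (end_b - start_b) / len(sb)
    return LocalAlignment(
        score=float(alignment.score),
        span_a=(start_a, end_a),
        span_b=(start_b, end_b),
        identity=matches / aligned_cols if aligned_cols else 0.0,
        coverage_longer=cov,
    )
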