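"""Duplicated-gene detection and chromosomal hotspot scanning.

A pair of genes is a duplication event when the local alignment of their
CDS covers more than 80% of the longer gene AND the identity of the
aligned region exceeds 80% — both strictly. A hotspot is a chromosomal
region holding five or more catalogued genes within (strictly) less than
5 Mb; reported hotspots are maximal, i.e. not contained in any larger
qualifying region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .alignment import Scoring, align_local
from .models import UNASSIGNED, GeneRecord, SeqEntry

IDENTITY_THRESHOLD = 0.80
COVERAGE_THRESHOLD = 0.80
HOTSPOT_MIN_GENES = 5
HOTSPOT_WINDOW_BP = 5_000_000
TANDEM_MAX_SEPARATION_BP = 100_000


@dataclass(frozen=True)
class DuplicationPair:
    """A qualifying duplicate pair; ``gene_a`` sorts before ``gene_b``."""

    gene_a: str
    gene_b: str
    identity: float
    coverage_longer: float
    tandem: bool = False

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort before gene_b")


@dataclass(frozen=True)
class Hotspot:
    """A maximal region of >=5 catalogued genes spanning < 5 Mb."""

    chromosome: str
    start: int
    end: int
    member_gene_ids: tuple[str, ...]


def detect_duplicates(
    records: list[GeneRecord],
    cds_seqs: dict[str, SeqEntry],
    identity_threshold: float = IDENTITY_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    scoring: Scoring | None = None,
) -> list[DuplicationPair]:
    """Evaluate all unordered gene pairs; keep strict 80/80 qualifiers."""
    for r in records:
        if r.gene_id not in cds_seqs:
            raise ValueError(f"no CDS sequence for gene {r.gene_id}")
    pairs: list[DuplicationPair] = []
    ids = sorted(r.gene_id for r in records)
    for i, ga in enumerate(ids):
        for gb in ids[i + 1:]:
            aln = align_local(cds_seqs[ga], cds_seqs[gb], scoring=scoring)
            if (
                aln.identity > identity_threshold
                and aln.coverage_longer > coverage_threshold
            ):
                pairs.append(
                    DuplicationPair(
                        gene_a=ga,
                        gene_b=gb,
                        identity=aln.identity,
                        coverage_longer=aln.coverage_longer,
                    )
                )
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))


def classify_tandem(
    pairs: list[DuplicationPair],
    records: list[GeneRecord],
    max_separation_bp: int = TANDEM_MAX_SEPARATION_BP,
) -> list[DuplicationPair]:
    """Flag pairs on the same chromosome separated by at most the cutoff.

    The gap is measured between the facing gene ends (0 for overlapping
    genes). The tandem cutoff is a convention, not a published value.
    """
    by_id = {r.gene_id: r for r in records}
    out = []
    for p in pairs:
        a, b = by_id[p.gene_a], by_id[p.gene_b]
        tandem = False
        if a.chromosome == b.chromosome:
            gap = max(a.start, b.start) - min(a.end, b.end) - 1
            tandem = max(gap, 0) <= max_separation_bp
        out.append(replace(p, tandem=tandem))
    return out


def find_hotspots(
    records: list[GeneRecord],
    min_genes: int = HOTSPOT_MIN_GENES,
    window_bp: int = HOTSPOT_WINDOW_BP,
) -> list[Hotspot]:
    """All maximal runs of >= ``min_genes`` family genes within < ``window_bp``.

    Genes lacking a family label are ignored. Per chromosome, genes are
    sorted by start; a run of consecutive genes qualifies when its span
    (last end - first start + 1) is strictly below ``window_bp``; runs
    contained in a larger qualifying run are suppressed. Maximal runs may
    overlap each other.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for r in records:
        if r.family == UNASSIGNED:
            continue
        by_chrom.setdefault(r.chromosome, []).append(r)

    hotspots: list[Hotspot] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.gene_id))
        n = len(genes)
        # max end among the first k genes, so a run's span uses the true
        # rightmost end even if a long gene precedes shorter ones
        runs: list[tuple[int, int]] = []
        for i in range(n):
            max_end = 0
            for j in range(i, n):
                max_end = max(max_end, genes[j].end)
                if j - i + 1 >= min_genes and max_end - genes[i].start + 1 < window_bp:
                    runs.append((i, j))
        maximal = [
            (i, j)
            for (i, j) in runs
            if not any((p <= i and j <= q and (p, q) != (i, j)) for (p, q) in runs)
        ]
        for i, j in sorted(maximal):
            members = genes[i : j + 1]
            hotspots.append(
                Hotspot(
                    chromosome=chrom,
                    start=members[0].start,
                    end=max(g.end for g in members),
                    member_gene_ids=tuple(g.gene_id for g in members),
                )
            )
    return hotspots


def write_hotspots_bed(hotspots: list[Hotspot], path) -> None:
    """BED output; start converts to 0-based half-open at this boundary."""
    with open(path, "w") as fh:
        for k, h in enumerate(hotspots, 1):
            fh.write(f"{h.chromosome}\t{h.start - 1}\t{h.end}\thotspot_{k}\n")
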