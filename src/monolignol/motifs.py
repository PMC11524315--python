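"""Promoter extraction and exact cis-element scanning.

Promoters are the 2000 bp immediately upstream of the annotated gene
start (the gene span stands proxy for the start codon; the annotation
model carries gene spans only). Motif scanning is exact matching under
IUPAC degeneracy on both strands — no position-weight scoring. The
bundled default vocabulary of 23 labelled motifs (MYB-, AP2-, bZIP-,
MADS-, NAC-, ARF- and WRKY-like tags) is a synthetic stand-in list for
fixture use; any user motif list is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .models import GeneRecord, SeqEntry

PROMOTER_LENGTH = 2000

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC DNA alphabet."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    offset: int  # 0-based within the promoter
    strand: str  # + | -


def extract_promoter(
    gene: GeneRecord,
    chromosome_seq: str,
    length: int = PROMOTER_LENGTH,
) -> SeqEntry:
    """Upstream ``length`` bp of a gene, strand-aware, edge-truncated.

    For a + gene starting at s the promoter is bases [s-length, s-1]; for
    a - gene ending at e it is the reverse complement of [e+1, e+length].
    At a chromosome edge the promoter is truncated (possibly to nothing,
    in which case a single-N placeholder entry is returned).
    """
    if length <= 0:
        raise ValueError("promoter length must be positive")
    n = len(chromosome_seq)
    if gene.end > n:
        raise ValueError(f"{gene.gene_id}: gene extends beyond chromosome")
    if gene.strand == "+":
        lo = max(gene.start - length, 1)
        seq = chromosome_seq[lo - 1 : gene.start - 1]
    else:
        hi = min(gene.end + length, n)
        seq = revcomp(chromosome_seq[gene.end : hi])
    return SeqEntry(
        id=f"{gene.gene_id}_promoter",
        residues=seq.upper() if seq else "N",
        alphabet="dna",
    )


def _iupac_regex(motif: str) -> re.Pattern:
    # character classes over ACGT only: N in the promoter matches nothing
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
        for c in motif
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def scan_motifs(
    promoter: SeqEntry, motifs: list[str], gene_id: str | None = None
) -> list[MotifHit]:
    """Every IUPAC match of each motif on both strands of a promoter.

    A - strand hit at offset k means the motif's reverse complement
    matches the + strand text at k. Overlapping hits are all reported,
    sorted by (motif, offset, strand).
    """
    seq = promoter.residues.upper()
    gid = gene_id or promoter.id.removesuffix("_promoter")
    hits: list[MotifHit] = []
    for motif in motifs:
        m = motif.upper()
        bad = set(m) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in motif {motif!r}: {sorted(bad)}")
        found = []
        for match in _iupac_regex(m).finditer(seq):
            found.append((match.start(), "+"))
        for match in _iupac_regex(revcomp(m)).finditer(seq):
            found.append((match.start(), "-"))
        for off, strand in sorted(found):
            hits.append(MotifHit(gene_id=gid, motif=motif, offset=off, strand=strand))
    return hits


def frequency_matrix(
    hits: list[MotifHit],
    grouping: str = "gene",
    gene_ids: list[str] | None = None,
    family_of: dict[str, str] | None = None,
    subset: list[str] | None = None,
) -> pd.DataFrame:
    """Hit counts per gene (or family) x motif.

    ``gene_ids`` fixes the row universe (zero rows included);
    ``subset`` restricts rows to a gene-id list (e.g. a xylem-specific
    catalogue) and must be drawn from the known genes.
    """
    if grouping not in ("gene", "family"):
        raise ValueError("grouping must be gene or family")
    universe = set(gene_ids) if gene_ids is not None else {h.gene_id for h in hits}
    if subset is not None:
        unknown = sorted(set(subset) - universe)
        if unknown:
            raise ValueError(f"unknown gene ids in subset: {unknown}")
        universe = set(subset)
    if grouping == "family" and family_of is None:
        raise ValueError("family grouping needs family_of")

    def row_of(gene: str) -> str:
        return family_of[gene] if grouping == "family" else gene

    motifs = sorted({h.motif for h in hits})
    rows = sorted({row_of(g) for g in universe})
    df = pd.DataFrame(0, index=rows, columns=motifs, dtype=int)
    for h in hits:
        if h.gene_id in universe:
            df.loc[row_of(h.gene_id), h.motif] += 1
    df.index.name = grouping
    return df


def load_default_motifs(path: str | Path | None = None) -> pd.DataFrame:
    """Motif list TSV (motif_id, iupac, tf_family); bundled list by default."""
    if path is None:
        src = resources.files("monolignol.data") / "default_motifs.tsv"
        df = pd.read_csv(src.open(), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"motif_id", "iupac", "tf_family"}
    if not required <= set(df.columns):
        raise ValueError(f"motif table needs columns {sorted(required)}")
    return df
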