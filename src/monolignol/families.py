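"""Assign candidate genes to the 11 monolignol enzyme families.

A candidate is assigned by best local-alignment score against per-family
reference sequences, gated by a required-domain check: each family carries
short protein patterns (a presence/absence stand-in for its Pfam domains)
and, when the gate is enabled, an assigned gene must contain at least one
of them as an exact substring. A raw alignment-score threshold plays the
role of a similarity-search E-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .alignment import Scoring, align_local
from .models import FAMILIES, UNASSIGNED, GeneRecord, SeqEntry

DEFAULT_MIN_SCORE = 100.0


@dataclass(frozen=True)
class FamilyReference:
    """Reference members and required domain patterns for one family."""

    family: str
    members: tuple[SeqEntry, ...]
    required_motifs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.family}: needs at least one member")
        if not all(self.required_motifs):
            raise ValueError(f"{self.family}: empty required motif")


def assign_family(
    query: SeqEntry,
    refs: list[FamilyReference],
    min_score: float = DEFAULT_MIN_SCORE,
    require_domain: bool = True,
    scoring: Scoring | None = None,
) -> str:
    """Best-scoring family above ``min_score``, else ``"unassigned"``.

    Ties on score are broken by higher identity, then by family label, so
    the result is independent of reference ordering.
    """
    best: tuple[float, float, str] | None = None  # (score, identity, label)
    for ref in refs:
        for member in ref.members:
            aln = align_local(query, member, scoring=scoring)
            key = (aln.score, aln.identity, ref.family)
            if best is None or (
                key[0] > best[0]
                or (key[0] == best[0] and key[1] > best[1])
                or (key[0] == best[0] and key[1] == best[1] and key[2] < best[2])
            ):
                best = key
    if best is None or best[0] < min_score:
        return UNASSIGNED
    family = best[2]
    if require_domain:
        ref = next(r for r in refs if r.family == family)
        seq = query.residues.upper()
        if not any(m.upper() in seq for m in ref.required_motifs):
            return UNASSIGNED
    return family


def count_table(
    records: list[GeneRecord], group_by: str = "species"
) -> pd.DataFrame:
    """Family-by-group gene counts with a Total column (Table-1 layout).

    ``group_by`` is ``"species"`` or ``"subgenome"`` (unplaced genes fall
    in an ``unmapped`` row).
    """
    if group_by not in ("species", "subgenome"):
        raise ValueError("group_by must be species or subgenome")
    rows: dict[str, dict[str, int]] = {}
    for r in records:
        if r.family == UNASSIGNED:
            raise ValueError(f"{r.gene_id}: unassigned family in count_table")
        if group_by == "species":
            group = r.species or "unknown"
        else:
            group = r.subgenome if r.subgenome != "none" else "unmapped"
        rows.setdefault(group, dict.fromkeys(FAMILIES, 0))
        rows[group][r.family] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FAMILIES))
    if df.empty:
        df = pd.DataFrame(columns=list(FAMILIES), dtype=int)
    df = df.fillna(0).astype(int)
    df["Total"] = df[list(FAMILIES)].sum(axis=1)
    df.index.name = "group"
    return df.sort_index()


def load_reference_count_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a published family-count table (bundled nine-species table by
    default) and append the Total column."""
    if path is None:
        src = resources.files("monolignol.data") / "reference_family_counts.tsv"
        df = pd.read_csv(src.open(), sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [f for f in FAMILIES if f not in df.columns]
    if missing:
        raise ValueError(f"count table missing families: {missing}")
    df = df[list(FAMILIES)].astype(int)
    df["Total"] = df[list(FAMILIES)].sum(axis=1)
    return df
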