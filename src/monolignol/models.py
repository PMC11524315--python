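"""Core domain types shared by every stage of the pipeline.

Coordinates are 1-based and inclusive throughout the package; conversion to
0-based half-open happens only inside writers (e.g. BED output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The eleven enzyme families of the monolignol branch of the
#: phenylpropanoid pathway.
FAMILIES: tuple[str, ...] = (
    "PAL", "C4H", "4CL", "HCT", "C3H", "CSE",
    "COMT", "F5H", "CCoAOMT", "CCR", "CAD",
)

UNASSIGNED = "unassigned"

_DNA = set("ACGTN")
_IUPAC_DNA = set("ACGTRYSWKMBDHVN-")   # '-' permitted for aligned rows
_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYX*-")


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One annotated gene: location, strand, family and sub-genome tag."""

    gene_id: str
    chromosome: str
    start: int  # 1-based, inclusive
    end: int    # inclusive, >= start
    strand: str = "+"
    family: str = UNASSIGNED
    subgenome: str = "none"
    species: str = ""

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"{self.gene_id}: chromosome must be nonempty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.gene_id}: invalid span {self.start}..{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.family != UNASSIGNED and self.family not in FAMILIES:
            raise ValueError(f"{self.gene_id}: unknown family {self.family!r}")
        if self.subgenome not in ("At", "Bt", "none"):
            raise ValueError(f"{self.gene_id}: subgenome must be At/Bt/none")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SeqEntry:
    """A named sequence; ``alphabet`` is ``"dna"`` or ``"protein"``."""

    id: str
    residues: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        if self.alphabet == "dna":
            bad = set(self.residues.upper()) - _IUPAC_DNA
        elif self.alphabet == "protein":
            bad = set(self.residues.upper()) - _PROTEIN
        else:
            raise ValueError(f"{self.id}: alphabet must be dna or protein")
        if bad:
            raise ValueError(
                f"{self.id}: residues {sorted(bad)} invalid for {self.alphabet}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SampleInfo:
    """One RNA-seq sample: genotype, replicate and the tall/short class."""

    sample_id: str
    genotype: str
    replicate: int
    height_class: str  # "tall" | "short"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"{self.sample_id}: replicate must be >= 1")
        if self.height_class not in ("tall", "short"):
            raise ValueError(
                f"{self.sample_id}: height_class must be tall or short"
            )


#: conversion constant of the spectrophotometric lignin assay (mg/g per
#: unit of ΔA per gram of dry weight)
LIGNIN_ASSAY_COEF = 2.184


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-genotype phenotype: height plus the lignin assay quantities.

    Lignin content may be given directly (mg/g) or derived from the
    absorbance difference ``delta_A`` and dry weight ``W`` as
    2.184 x ΔA / W.
    """

    genotype: str
    height_cm: float
    delta_A: float | None = None
    dry_weight_g: float | None = None
    lignin_mg_per_g: float | None = None

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ValueError(f"{self.genotype}: height must be positive")
        if self.delta_A is not None and self.delta_A < 0:
            raise ValueError(f"{self.genotype}: delta_A must be >= 0")
        if self.dry_weight_g is not None and self.dry_weight_g <= 0:
            raise ValueError(f"{self.genotype}: dry weight must be positive")
        if (
            self.delta_A is not None
            and self.dry_weight_g is not None
            and self.lignin_mg_per_g is not None
        ):
            expect = LIGNIN_ASSAY_COEF * self.delta_A / self.dry_weight_g
            if abs(expect - self.lignin_mg_per_g) > 1e-6 * max(1.0, expect):
                raise ValueError(
                    f"{self.genotype}: lignin {self.lignin_mg_per_g} "
                    f"inconsistent with 2.184*dA/W = {expect}"
                )

    @property
    def lignin(self) -> float:
        if self.lignin_mg_per_g is not None:
            return self.lignin_mg_per_g
        if self.delta_A is None or self.dry_weight_g is None:
            raise ValueError(f"{self.genotype}: no lignin measurement")
        return LIGNIN_ASSAY_COEF * self.delta_A / self.dry_weight_g


@dataclass
class GroundTruth:
    """Planted entities of a synthetic study, keyed for recovery tests."""

    family_of: dict[str, str] = field(default_factory=dict)
    planted_duplicate_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_tandem_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_hotspots: list[tuple[str, int, int]] = field(default_factory=list)
    planted_deg_ids: dict[str, float] = field(default_factory=dict)  # id -> log2fc
    planted_motif_hits: list[tuple[str, str, int, str]] = field(
        default_factory=list
    )  # (gene_id, motif, offset, strand)
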