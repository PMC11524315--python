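"""Readers and writers for the plain-text formats the pipeline touches.

GFF3 here covers gene features only; the custom attributes ``family=`` and
``subgenome=`` carry the pipeline's annotations so that one file is the
canonical catalogue. When the ``subgenome`` attribute is absent it is
inferred from the chromosome name (leading ``A``/``B`` after an optional
``chr`` prefix), mirroring the A01-B19 naming of a tetraploid assembly.
"""

from __future__ import annotations

import urllib.parse
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneRecord, PhenotypeRecord, SampleInfo, SeqEntry, UNASSIGNED


class ParseError(ValueError):
    """Raised when an input file is malformed; message names the line."""


def _infer_subgenome(chromosome: str) -> str:
    name = chromosome[3:] if chromosome.lower().startswith("chr") else chromosome
    if name[:1] == "A":
        return "At"
    if name[:1] == "B":
        return "Bt"
    return "none"


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GeneRecord]:
    """Read gene features from a GFF3 file into :class:`GeneRecord` objects."""
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attr = {}
            for item in attrs.split(";"):
                if not item:
                    continue
                if "=" not in item:
                    raise ParseError(f"{path}:{lineno}: bad attribute {item!r}")
                key, _, val = item.partition("=")
                attr[key.strip()] = urllib.parse.unquote(val.strip())
            if "ID" not in attr:
                raise ParseError(f"{path}:{lineno}: gene feature lacks ID")
            if end < start:
                raise ParseError(f"{path}:{lineno}: end < start")
            records.append(
                GeneRecord(
                    gene_id=attr["ID"],
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-" else "+",
                    family=attr.get("family", UNASSIGNED),
                    subgenome=attr.get("subgenome", _infer_subgenome(chrom)),
                    species=attr.get("species", ""),
                )
            )
    return records


def write_gff3(records: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = [f"ID={r.gene_id}"]
            if r.family != UNASSIGNED:
                attrs.append(f"family={r.family}")
            # always explicit so read_gff3's name-based inference never
            # has to guess on round trips
            attrs.append(f"subgenome={r.subgenome}")
            if r.species:
                attrs.append(f"species={r.species}")
            fh.write(
                f"{r.chromosome}\tmonolignol\tgene\t{r.start}\t{r.end}"
                f"\t.\t{r.strand}\t.\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SeqEntry]:
    entries = [
        SeqEntry(id=rec.id, residues=str(rec.seq), alphabet=alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: dict[str, int] = {}
    for e in entries:
        seen[e.id] = seen.get(e.id, 0) + 1
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ParseError(f"{path}: duplicate FASTA ids: {', '.join(dups)}")
    return entries


def write_fasta(entries: list[SeqEntry], path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(e.residues), id=e.id, description="") for e in entries
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Count matrix + sample sheet


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """TSV with columns sample_id, genotype, replicate, height_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "replicate", "height_class"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    samples = [
        SampleInfo(
            sample_id=row.sample_id,
            genotype=row.genotype,
            replicate=int(row.replicate),
            height_class=row.height_class,
        )
        for row in df.itertuples()
    ]
    keys = [(s.genotype, s.replicate) for s in samples]
    if len(set(keys)) != len(keys):
        raise ParseError(f"{path}: duplicate (genotype, replicate) pairs")
    return samples


def write_sample_sheet(samples: list[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.sample_id, s.genotype, s.replicate, s.height_class)
            for s in samples
        ],
        columns=["sample_id", "genotype", "replicate", "height_class"],
    ).to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path, samples: list[SampleInfo] | None = None
) -> pd.DataFrame:
    """Read a gene x sample TSV of nonnegative integer read counts.

    If ``samples`` is given the header must match the sample sheet exactly
    (same ids, any order is rejected to keep column order meaningful).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ParseError(f"{path}: missing cells in count matrix")
    arr = df.to_numpy()
    if not ((arr >= 0).all() and (arr == arr.astype(int)).all()):
        raise ParseError(f"{path}: counts must be nonnegative integers")
    df = df.astype(int)
    if samples is not None:
        expected = [s.sample_id for s in samples]
        if list(df.columns) != expected:
            raise ParseError(
                f"{path}: header {list(df.columns)} does not match sample "
                f"sheet {expected}"
            )
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """TSV with columns genotype, height_cm and either lignin_mg_per_g or
    (delta_A, dry_weight_g) or all three."""
    df = pd.read_csv(path, sep="\t")
    if "genotype" not in df.columns or "height_cm" not in df.columns:
        raise ParseError(f"{path}: need genotype and height_cm columns")
    out = []
    for row in df.itertuples():
        out.append(
            PhenotypeRecord(
                genotype=str(row.genotype),
                height_cm=float(row.height_cm),
                delta_A=float(row.delta_A) if "delta_A" in df.columns else None,
                dry_weight_g=(
                    float(row.dry_weight_g) if "dry_weight_g" in df.columns else None
                ),
                lignin_mg_per_g=(
                    float(row.lignin_mg_per_g)
                    if "lignin_mg_per_g" in df.columns
                    else None
                ),
            )
        )
    return out


def write_phenotypes(records: list[PhenotypeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.genotype, r.height_cm, r.delta_A, r.dry_weight_g, r.lignin)
            for r in records
        ],
        columns=["genotype", "height_cm", "delta_A", "dry_weight_g", "lignin_mg_per_g"],
    ).to_csv(path, sep="\t", index=False)
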