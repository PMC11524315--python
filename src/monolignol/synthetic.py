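"""Seeded synthetic study generator with recorded ground truth.

Emulates the study design the pipeline targets: a tetraploid genome with
At/Bt sub-genomes (19 chromosomes each), ~200 genes across the 11
monolignol families with planted tandem duplicates and gene hotspots, an
RNA-seq experiment of 4 genotypes x 3 replicates with negative-binomial
counts and planted differentially expressed genes (mostly down-regulated
in tall genotypes), genotype phenotypes with a negative height-lignin
correlation, and 2000-bp promoters with planted cis-element motifs.

Every generator is deterministic under its seed (byte-identical files),
and every planted entity is recorded in :class:`GroundTruth` so the
downstream stages can be scored against it. Sequences are substitution-
evolved random strings: no codon structure, no indels — duplicate-pair
identity and coverage are therefore controlled exactly, which is what
makes the strict 80/80 rule testable at its boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .families import FamilyReference
from .models import (
    FAMILIES,
    LIGNIN_ASSAY_COEF,
    GeneRecord,
    GroundTruth,
    PhenotypeRecord,
    SampleInfo,
    SeqEntry,
)
from .motifs import IUPAC, revcomp

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

#: nine-taxon panel and its group labels (two herbaceous monocots, two
#: herbaceous dicots, five woody species)
TAXA: dict[str, str] = {
    "Osativa": "monocot",
    "Zmays": "monocot",
    "Athaliana": "herb_dicot",
    "Slycopersicum": "herb_dicot",
    "Ssuchowensis": "woody",
    "Spurpurea": "woody",
    "Peuphratica": "woody",
    "Ptrichocarpa": "woody",
    "Smatsudana": "woody",
}

#: family evolutionary classes planted in the synthetic alignments
FAMILY_CLASSES: dict[str, str] = {
    "PAL": "Ia", "C4H": "Ia", "CCoAOMT": "Ia",
    "CCR": "Ib", "C3H": "Ib",
    "HCT": "II", "4CL": "II", "CSE": "II",
    "CAD": "II", "F5H": "II", "COMT": "II",
}

# Guide topologies per class over the nine taxa (nested tuples). Ia keeps
# the monocots on one side with the herbaceous dicots interleaved among the
# woody taxa (no separate dicot clade); Ib gives each group its own clade;
# II interleaves all three groups.
_GUIDE_IA = (
    ("Osativa", "Zmays"),
    ("Athaliana", (("Ssuchowensis", "Spurpurea"), ("Slycopersicum",
     ("Peuphratica", ("Ptrichocarpa", "Smatsudana"))))),
)
_GUIDE_IB = (
    ("Osativa", "Zmays"),
    (("Athaliana", "Slycopersicum"),
     (("Ssuchowensis", "Spurpurea"),
      ("Peuphratica", ("Ptrichocarpa", "Smatsudana")))),
)
_GUIDE_II = (
    (("Osativa", "Ptrichocarpa"), ("Athaliana", "Ssuchowensis")),
    (("Zmays", "Peuphratica"),
     ("Slycopersicum", ("Spurpurea", "Smatsudana"))),
)
_GUIDES = {"Ia": _GUIDE_IA, "Ib": _GUIDE_IB, "II": _GUIDE_II}


@dataclass(frozen=True)
class HotspotSpec:
    chromosome: str
    n_genes: int
    span_bp: int  # planted span, must be < 5 Mb

    def __post_init__(self) -> None:
        if self.n_genes < 5:
            raise ValueError("hotspot needs >= 5 genes")
        if not (0 < self.span_bp < 5_000_000):
            raise ValueError("hotspot span must be in (0, 5 Mb)")


@dataclass(frozen=True)
class DuplicateSpec:
    identity: float
    coverage: float = 1.0
    tandem: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0, 1]")


@dataclass
class StudyConfig:
    """Default scale: 38 chromosomes of 10-20 Mb, ~200 genes."""

    n_chrom_per_subgenome: int = 19
    chrom_len_range: tuple[int, int] = (10_000_000, 20_000_000)
    genes_per_family: int = 18
    n_unplaced: int = 26
    protein_len: int = 240
    cds_len: int = 1200
    family_divergence: float = 0.12
    hotspots: tuple[HotspotSpec, ...] = (
        HotspotSpec("chrA01", 6, 3_500_000),
        HotspotSpec("chrA08", 5, 3_000_000),
        HotspotSpec("chrA11", 5, 2_500_000),
        HotspotSpec("chrB08", 6, 3_500_000),
        HotspotSpec("chrB11", 5, 3_000_000),
        HotspotSpec("chrB16", 6, 4_000_000),
        HotspotSpec("chrB18", 5, 2_500_000),
    )
    duplicates: tuple[DuplicateSpec, ...] = (
        DuplicateSpec(0.95, 1.0, tandem=True),
        DuplicateSpec(0.95, 1.0, tandem=True),
        DuplicateSpec(0.90, 1.0, tandem=True),
        DuplicateSpec(0.90, 0.95, tandem=True),
        DuplicateSpec(0.85, 1.0, tandem=False),
        DuplicateSpec(0.85, 0.90, tandem=False),
    )
    # RNA-seq design: two short and two tall genotypes, three replicates
    genotypes: tuple[tuple[str, str], ...] = (
        ("Yanjiang", "short"), ("FS", "short"), ("9901", "tall"), ("FH", "tall"),
    )
    n_replicates: int = 3
    expressed_fraction: float = 0.6
    n_deg_up_short: int = 19
    n_deg_up_tall: int = 4
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    target_correlation: float = -0.62
    promoter_length: int = 2000
    motif_plant_rate: float = 0.5
    n_xylem_genes: int = 42
    msa_columns: int = 500


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = DNA) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _mutate(
    rng: np.random.Generator,
    seq: str,
    n_mut: int,
    alphabet: str,
    protected: tuple[int, int] | None = None,
) -> str:
    """Substitute exactly ``n_mut`` distinct positions (never inside
    ``protected`` and never in the outermost 10 residues, so optimal local
    alignment keeps the full-length path)."""
    candidates = [
        i
        for i in range(10, len(seq) - 10)
        if protected is None or not (protected[0] <= i < protected[1])
    ]
    if n_mut > len(candidates):
        raise ValueError("too many mutations requested")
    positions = rng.choice(candidates, size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [c for c in alphabet if c != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def engineer_duplicate_pair(
    seed: int,
    length: int = 600,
    identity: float = 0.80,
    coverage: float = 1.0,
    max_tries: int = 50,
) -> tuple[SeqEntry, SeqEntry]:
    """A CDS pair whose *measured* local-alignment identity and coverage
    equal the targets exactly.

    Substitution patterns occasionally admit a gapped local alignment one
    point better than the planted gapless one, which shifts the measured
    identity slightly; this helper redraws until the optimal alignment is
    the planted one, so threshold-boundary pairs (e.g. identity exactly
    0.80) are constructed faithfully.
    """
    from .alignment import align_local

    if not (0.0 < identity <= 1.0 and 0.0 < coverage <= 1.0):
        raise ValueError("identity and coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    copy_len = int(round(coverage * length))
    n_mut = int(round((1.0 - identity) * copy_len))
    target_ident = (copy_len - n_mut) / copy_len
    target_cov = copy_len / length
    for _ in range(max_tries):
        parent = _random_seq(rng, length)
        copy = _mutate(rng, parent[:copy_len], n_mut, DNA)
        a = SeqEntry(id="parent", residues=parent, alphabet="dna")
        b = SeqEntry(id="copy", residues=copy, alphabet="dna")
        aln = align_local(a, b)
        if (
            abs(aln.identity - target_ident) < 1e-12
            and abs(aln.coverage_longer - target_cov) < 1e-12
        ):
            return a, b
    raise RuntimeError("could not engineer an exact-identity pair")


def make_family_references(
    seed: int, protein_len: int = 240, motif_len: int = 8
) -> list[FamilyReference]:
    """One random ancestor protein per family, each carrying a
    family-specific required-domain pattern at a fixed interior site."""
    rng = np.random.default_rng(seed)
    refs = []
    for family in FAMILIES:
        ancestor = _random_seq(rng, protein_len, PROTEIN_ALPHABET)
        pos = protein_len // 3
        motif = _random_seq(rng, motif_len, PROTEIN_ALPHABET)
        ancestor = ancestor[:pos] + motif + ancestor[pos + motif_len:]
        refs.append(
            FamilyReference(
                family=family,
                members=(SeqEntry(id=f"{family}_ref", residues=ancestor,
                                  alphabet="protein"),),
                required_motifs=(motif,),
            )
        )
    return refs


# ---------------------------------------------------------------------------
# genome


@dataclass
class SyntheticGenome:
    records: list[GeneRecord]
    proteins: list[SeqEntry]
    cds: list[SeqEntry]
    refs: list[FamilyReference]
    truth: GroundTruth


def generate_genome(
    seed: int, config: StudyConfig | None = None
) -> SyntheticGenome:
    """Plant the gene catalogue: hotspots, duplicate pairs, unplaced genes
    and spaced background genes, with per-gene protein and CDS sequences."""
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    truth = GroundTruth()

    chrom_names = [
        f"chr{sub}{i:02d}"
        for sub in ("A", "B")
        for i in range(1, cfg.n_chrom_per_subgenome + 1)
    ]
    chrom_len = {
        name: int(rng.integers(*cfg.chrom_len_range)) for name in chrom_names
    }
    for spec in cfg.hotspots:
        if spec.chromosome not in chrom_len:
            raise ValueError(f"hotspot chromosome {spec.chromosome} not in genome")

    # family slots, shuffled
    slots = [f for f in FAMILIES for _ in range(cfg.genes_per_family)]
    rng.shuffle(slots)
    n_total = len(slots)
    n_hot = sum(s.n_genes for s in cfg.hotspots)
    n_dup = len(cfg.duplicates)
    n_background = n_total - n_hot - cfg.n_unplaced - n_dup
    if n_background < n_dup:
        raise ValueError("config leaves too few background genes")

    refs = make_family_references(seed, protein_len=cfg.protein_len)
    ref_by_family = {r.family: r for r in refs}

    placements: list[dict] = []  # chromosome,start,end,strand,family,role
    gene_span = lambda: int(rng.integers(2_000, 6_000))

    # hotspots: n_genes placed within span_bp, spaced evenly + jitter
    slot_iter = iter(slots)
    for spec in cfg.hotspots:
        clen = chrom_len[spec.chromosome]
        region_start = int(rng.integers(1, clen - spec.span_bp - 10_000))
        step = spec.span_bp // (spec.n_genes - 1)
        members = []
        for k in range(spec.n_genes):
            start = region_start + k * step + int(rng.integers(0, step // 4 + 1))
            span = gene_span()
            members.append(
                dict(
                    chromosome=spec.chromosome, start=start, end=start + span,
                    strand="+" if rng.random() < 0.5 else "-",
                    family=next(slot_iter), role="hotspot",
                )
            )
        # clamp the planted region span strictly below 5 Mb
        span = max(m["end"] for m in members) - members[0]["start"] + 1
        if span >= 5_000_000:
            raise ValueError("hotspot spec produced an oversized region")
        placements.extend(members)
        truth.planted_hotspots.append(
            (spec.chromosome, members[0]["start"], max(m["end"] for m in members))
        )

    # background genes: >=1.5 Mb apart from each other, >=5 Mb from any
    # hotspot gene, so planted hotspots stay the only qualifying regions
    hot_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in placements:
        hot_by_chrom.setdefault(p["chromosome"], []).append((p["start"], p["end"]))
    bg_by_chrom: dict[str, list[int]] = {}

    def place_background() -> dict:
        for _ in range(1000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            clen = chrom_len[chrom]
            start = int(rng.integers(1, clen - 10_000))
            if any(
                start < e + 5_000_000 and start > s - 5_000_000
                for (s, e) in hot_by_chrom.get(chrom, [])
            ):
                continue
            if any(abs(start - s) < 1_500_000 for s in bg_by_chrom.get(chrom, [])):
                continue
            bg_by_chrom.setdefault(chrom, []).append(start)
            span = gene_span()
            return dict(
                chromosome=chrom, start=start, end=start + span,
                strand="+" if rng.random() < 0.5 else "-",
                family=None, role="background",
            )
        raise RuntimeError("could not place background gene; genome too dense")

    background = []
    for _ in range(n_background):
        p = place_background()
        p["family"] = next(slot_iter)
        background.append(p)
    placements.extend(background)

    # duplicate copies: parent drawn from background, copy placed tandem
    # (within 100 kb) or on another chromosome
    dup_parents = rng.choice(len(background), size=n_dup, replace=False)
    dup_infos = []
    for spec, parent_idx in zip(cfg.duplicates, dup_parents):
        parent = background[int(parent_idx)]
        span = gene_span()
        if spec.tandem:
            start = parent["end"] + int(rng.integers(5_000, 80_000))
        else:
            others = [c for c in chrom_names if c != parent["chromosome"]]
            chrom = others[int(rng.integers(len(others)))]
            for _ in range(1000):
                start = int(rng.integers(1, chrom_len[chrom] - 10_000))
                if not any(
                    start < e + 5_000_000 and start > s - 5_000_000
                    for (s, e) in hot_by_chrom.get(chrom, [])
                ) and not any(
                    abs(start - s) < 1_500_000 for s in bg_by_chrom.get(chrom, [])
                ):
                    break
            else:
                raise RuntimeError("could not place duplicate copy")
            bg_by_chrom.setdefault(chrom, []).append(start)
        copy = dict(
            chromosome=parent["chromosome"] if spec.tandem else chrom,
            start=start, end=start + span,
            strand=parent["strand"], family=parent["family"], role="dup_copy",
        )
        placements.append(copy)
        dup_infos.append((parent, copy, spec))

    # unplaced genes on scaffolds
    for k in range(cfg.n_unplaced):
        span = gene_span()
        placements.append(
            dict(
                chromosome=f"scaffold{k + 1:03d}", start=1_000, end=1_000 + span,
                strand="+", family=next(slot_iter), role="unplaced",
            )
        )

    # stable ids in genome order
    order = sorted(
        range(len(placements)),
        key=lambda i: (
            placements[i]["chromosome"].startswith("scaffold"),
            placements[i]["chromosome"],
            placements[i]["start"],
        ),
    )
    ids = {}
    for rank, i in enumerate(order, start=1):
        ids[i] = f"SmLG{rank:03d}"

    records: list[GeneRecord] = []
    for i in order:
        p = placements[i]
        chrom = p["chromosome"]
        sub = "none"
        if chrom.startswith("chrA"):
            sub = "At"
        elif chrom.startswith("chrB"):
            sub = "Bt"
        records.append(
            GeneRecord(
                gene_id=ids[i], chromosome=chrom, start=p["start"], end=p["end"],
                strand=p["strand"], family=p["family"], subgenome=sub,
                species="Smatsudana",
            )
        )
        truth.family_of[ids[i]] = p["family"]

    # sequences: proteins diverge from the family ancestor with the domain
    # motif protected; CDS are independent random DNA except duplicates
    idx_of = {id(placements[i]): i for i in range(len(placements))}
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    motif_site = (cfg.protein_len // 3, cfg.protein_len // 3 + 8)
    for i in order:
        p = placements[i]
        gid = ids[i]
        ancestor = ref_by_family[p["family"]].members[0].residues
        n_mut = int(round(cfg.family_divergence * cfg.protein_len))
        proteins[gid] = _mutate(rng, ancestor, n_mut, PROTEIN_ALPHABET, motif_site)
        cds[gid] = _random_seq(rng, cfg.cds_len)

    for parent, copy, spec in dup_infos:
        pid, cid = ids[idx_of[id(parent)]], ids[idx_of[id(copy)]]
        parent_cds = cds[pid]
        copy_len = int(round(spec.coverage * len(parent_cds)))
        copy_seq = parent_cds[:copy_len]
        n_mut = int(round((1.0 - spec.identity) * copy_len))
        cds[cid] = _mutate(rng, copy_seq, n_mut, DNA)
        # protein: fresh mutated ancestor already assigned; keep it
        pair = tuple(sorted((pid, cid)))
        truth.planted_duplicate_pairs.add(pair)
        if spec.tandem:
            truth.planted_tandem_pairs.add(pair)

    return SyntheticGenome(
        records=records,
        proteins=[
            SeqEntry(id=g, residues=proteins[g], alphabet="protein")
            for g in sorted(proteins)
        ],
        cds=[SeqEntry(id=g, residues=cds[g], alphabet="dna") for g in sorted(cds)],
        refs=refs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# counts


def make_samples(config: StudyConfig | None = None) -> list[SampleInfo]:
    cfg = config or StudyConfig()
    return [
        SampleInfo(
            sample_id=f"{geno}_{rep}", genotype=geno, replicate=rep,
            height_class=height,
        )
        for geno, height in cfg.genotypes
        for rep in range(1, cfg.n_replicates + 1)
    ]


def generate_counts(
    seed: int,
    gene_ids: list[str],
    samples: list[SampleInfo],
    planted_degs: dict[str, float],
    nb_dispersion: float = 0.05,
    base_mean: float | dict[str, float] = 500.0,
):
    """Negative-binomial counts with planted tall-vs-short effects.

    ``planted_degs`` maps gene id to the log2 fold change of the tall
    group relative to the short group; other genes share one mean. The
    NB is parameterized mean/dispersion (variance = mu + alpha mu^2).
    """
    import pandas as pd

    if nb_dispersion <= 0:
        raise ValueError("dispersion must be positive")
    unknown = set(planted_degs) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted DEGs not in gene list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_inv = 1.0 / nb_dispersion  # NB size parameter

    def mean_of(gene: str) -> float:
        if isinstance(base_mean, dict):
            return float(base_mean[gene])
        return float(base_mean)

    data = np.zeros((len(gene_ids), len(samples)), dtype=int)
    for gi, gene in enumerate(gene_ids):
        mu_short = mean_of(gene)
        mu_tall = mu_short * 2.0 ** planted_degs.get(gene, 0.0)
        for si, sample in enumerate(samples):
            mu = mu_tall if sample.height_class == "tall" else mu_short
            if mu <= 0:
                data[gi, si] = 0
            else:
                p = n_inv / (n_inv + mu)
                data[gi, si] = int(rng.negative_binomial(n_inv, p))
    return pd.DataFrame(
        data, index=pd.Index(gene_ids, name="gene_id"),
        columns=[s.sample_id for s in samples],
    )


# ---------------------------------------------------------------------------
# promoters


def generate_promoters(
    seed: int,
    gene_ids: list[str],
    motif_vocabulary: list[tuple[str, str]],
    plant_rate: float = 0.5,
    length: int = 2000,
) -> tuple[list[SeqEntry], list[tuple[str, str, int, str]]]:
    """Random promoters with motifs planted at recorded offsets/strands.

    ``motif_vocabulary`` is (motif_id, iupac) pairs; each motif is planted
    in each promoter with probability ``plant_rate``. Planted hits are
    recorded as (gene_id, iupac, offset, strand); chance background
    matches are possible and deliberately not recorded.
    """
    if not (0.0 <= plant_rate <= 1.0):
        raise ValueError("plant_rate must be in [0, 1]")
    for _mid, iupac in motif_vocabulary:
        if len(iupac) > length:
            raise ValueError(f"motif {iupac} longer than promoter")
        bad = set(iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in {iupac}: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    entries: list[SeqEntry] = []
    hits: list[tuple[str, str, int, str]] = []
    for gene in gene_ids:
        seq = list(_random_seq(rng, length))
        occupied: list[tuple[int, int]] = []
        for _mid, iupac in motif_vocabulary:
            if rng.random() >= plant_rate:
                continue
            m = iupac.upper()
            concrete = "".join(
                sorted(IUPAC[c])[int(rng.integers(len(IUPAC[c])))] for c in m
            )
            # keep planted instances disjoint so none is clobbered by a
            # later insertion (ground truth stays exactly recoverable)
            for _ in range(200):
                offset = int(rng.integers(0, length - len(m) + 1))
                if all(
                    offset + len(m) <= s or offset >= e for s, e in occupied
                ):
                    break
            else:
                raise RuntimeError("promoter too crowded to plant motif")
            occupied.append((offset, offset + len(m)))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = concrete if strand == "+" else revcomp(concrete)
            seq[offset : offset + len(m)] = list(insert)
            hits.append((gene, iupac, offset, strand))
        entries.append(
            SeqEntry(id=f"{gene}_promoter", residues="".join(seq), alphabet="dna")
        )
    return entries, hits


# ---------------------------------------------------------------------------
# phenotypes


def generate_phenotypes(
    seed: int,
    genotypes: list[tuple[str, str]] | None = None,
    target_correlation: float = -0.62,
    max_tries: int = 10_000,
) -> list[PhenotypeRecord]:
    """Per-genotype heights and lignin values with a controlled Pearson r.

    Heights reflect the genotype's height class; lignin is drawn so the
    sample correlation across genotypes lands within +-0.1 of the target
    (rejection sampling). ΔA and W are back-computed so that
    lignin = 2.184 x ΔA / W holds exactly.
    """
    genos = list(genotypes or StudyConfig().genotypes)
    if len(genos) < 3:
        raise ValueError("need at least 3 genotypes for a correlation target")
    if not (-1.0 <= target_correlation <= 1.0):
        raise ValueError("target correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    heights = np.array([
        rng.normal(170, 20) if cls == "tall" else rng.normal(95, 20)
        for _name, cls in genos
    ])
    zh = (heights - heights.mean()) / heights.std()
    t = target_correlation
    for _ in range(max_tries):
        e = rng.normal(size=len(genos))
        e = (e - e.mean()) / e.std()
        z = t * zh + math.sqrt(max(0.0, 1.0 - t * t)) * e
        lignin = np.clip(600.0 + 300.0 * z, 50.0, None)
        r = float(np.corrcoef(heights, lignin)[0, 1])
        if abs(r - t) <= 0.1:
            break
    else:
        raise RuntimeError("could not reach target correlation")
    out = []
    for (name, _cls), h, lg in zip(genos, heights, lignin):
        w = float(rng.uniform(0.8, 1.5))
        delta_a = float(lg) * w / LIGNIN_ASSAY_COEF
        out.append(
            PhenotypeRecord(
                genotype=name, height_cm=round(float(h), 2),
                delta_A=delta_a, dry_weight_g=w,
                lignin_mg_per_g=LIGNIN_ASSAY_COEF * delta_a / w,
            )
        )
    return out


# ---------------------------------------------------------------------------
# family alignments


def _evolve(rng: np.random.Generator, seq: str, p_sub: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < p_sub:
            choices = [c for c in PROTEIN_ALPHABET if c != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _simulate_on_guide(
    rng: np.random.Generator, guide, root_seq: str, p_internal: float,
    p_terminal: float, out: dict[str, str],
) -> None:
    if isinstance(guide, str):
        out[guide] = _evolve(rng, root_seq, p_terminal)
        return
    for child in guide:
        child_seq = _evolve(rng, root_seq, p_internal)
        _simulate_on_guide(rng, child, child_seq, p_internal, p_terminal, out)


def generate_family_msas(
    seed: int, config: StudyConfig | None = None
) -> dict[str, "object"]:
    """One aligned nine-taxon protein MSA per family, simulated along a
    guide topology matching the family's planted class (Ia/Ib/II)."""
    from .phylogeny import MSA

    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    msas: dict[str, MSA] = {}
    for family in FAMILIES:
        cls = FAMILY_CLASSES[family]
        root = _random_seq(rng, cfg.msa_columns, PROTEIN_ALPHABET)
        leaves: dict[str, str] = {}
        _simulate_on_guide(rng, _GUIDES[cls], root, 0.06, 0.05, leaves)
        ids = [f"{family}_{taxon}" for taxon in TAXA]
        msas[family] = MSA(
            ids=ids,
            rows=[leaves[taxon] for taxon in TAXA],
            group_of={f"{family}_{t}": g for t, g in TAXA.items()},
        )
    return msas


# ---------------------------------------------------------------------------
# full study


def generate_study(seed: int, outdir: str | Path, config: StudyConfig | None = None) -> GroundTruth:
    """Write the complete synthetic study to ``outdir`` and return truth.

    Child seeds for each stage are derived deterministically from the
    master seed; the same seed always yields byte-identical files.
    """
    from . import io as mio
    from .io import write_counts, write_fasta, write_gff3

    cfg = config or StudyConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = generate_genome(seed, cfg)
    truth = genome.truth
    gene_ids = [r.gene_id for r in genome.records]

    write_gff3(genome.records, outdir / "genome.gff3")
    write_fasta(genome.proteins, outdir / "proteins.faa")
    write_fasta(genome.cds, outdir / "cds.fna")
    ref_entries = [m for r in genome.refs for m in r.members]
    write_fasta(ref_entries, outdir / "family_refs.faa")
    with open(outdir / "required_motifs.tsv", "w") as fh:
        fh.write("family\tmotif\n")
        for r in genome.refs:
            for m in r.required_motifs:
                fh.write(f"{r.family}\t{m}\n")

    samples = make_samples(cfg)
    mio.write_sample_sheet(samples, outdir / "samples.tsv")

    rng = np.random.default_rng(seed + 1)
    n_expressed = int(round(cfg.expressed_fraction * len(gene_ids)))
    expressed = sorted(
        rng.choice(gene_ids, size=n_expressed, replace=False).tolist()
    )
    # genes outside the expressed set are silent in this tissue; expressed
    # means are lognormal so libraries are deep enough that one stray read
    # cannot clear the FPKM filter
    base_mean = {g: 0.0 for g in gene_ids}
    for g in expressed:
        base_mean[g] = float(np.exp(rng.normal(np.log(5000.0), 0.8)))
    deg_pool = list(expressed)
    rng.shuffle(deg_pool)
    n_deg = cfg.n_deg_up_short + cfg.n_deg_up_tall
    for k, g in enumerate(deg_pool[:n_deg]):
        lfc = -cfg.deg_log2fc if k < cfg.n_deg_up_short else cfg.deg_log2fc
        truth.planted_deg_ids[g] = lfc

    counts = generate_counts(
        seed + 2, gene_ids, samples, truth.planted_deg_ids,
        nb_dispersion=cfg.nb_dispersion, base_mean=base_mean,
    )
    write_counts(counts, outdir / "counts.tsv")
    with open(outdir / "gene_lengths.tsv", "w") as fh:
        fh.write("gene_id\tlength_bp\n")
        for r in genome.records:
            fh.write(f"{r.gene_id}\t{cfg.cds_len}\n")

    phenos = generate_phenotypes(
        seed + 3, list(cfg.genotypes), cfg.target_correlation
    )
    mio.write_phenotypes(phenos, outdir / "phenotypes.tsv")

    from .motifs import load_default_motifs

    vocab_df = load_default_motifs()
    vocab = list(zip(vocab_df.motif_id, vocab_df.iupac))
    promoters, planted_hits = generate_promoters(
        seed + 4, gene_ids, vocab, cfg.motif_plant_rate, cfg.promoter_length
    )
    write_fasta(promoters, outdir / "promoters.fna")
    truth.planted_motif_hits = planted_hits

    xylem = sorted(
        np.random.default_rng(seed + 5)
        .choice(gene_ids, size=min(cfg.n_xylem_genes, len(gene_ids)), replace=False)
        .tolist()
    )
    with open(outdir / "xylem_genes.txt", "w") as fh:
        fh.write("\n".join(xylem) + "\n")

    msas = generate_family_msas(seed + 6, cfg)
    for family, msa in msas.items():
        write_fasta(
            [SeqEntry(id=i, residues=r, alphabet="protein")
             for i, r in zip(msa.ids, msa.rows)],
            outdir / f"msa_{family}.faa",
        )
    with open(outdir / "taxon_groups.tsv", "w") as fh:
        fh.write("taxon\tgroup\n")
        for taxon, group in TAXA.items():
            fh.write(f"{taxon}\t{group}\n")

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "family_of": truth.family_of,
                "planted_duplicate_pairs": sorted(
                    list(p) for p in truth.planted_duplicate_pairs
                ),
                "planted_tandem_pairs": sorted(
                    list(p) for p in truth.planted_tandem_pairs
                ),
                "planted_hotspots": truth.planted_hotspots,
                "planted_deg_ids": truth.planted_deg_ids,
                "planted_motif_hits": truth.planted_motif_hits,
                "family_classes": FAMILY_CLASSES,
                "xylem_genes": xylem,
            },
            fh, indent=1, sort_keys=True,
        )
    return truth
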