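"""Stage orchestration: one config, deterministic outputs, a run manifest.

Each stage reads the study directory, writes its tables under the output
directory and returns a JSON-serializable summary; ``run_all`` chains
every stage and writes a single ``summary.json`` whose numbers all come
from the stage outputs. Reruns with the same config and seed produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .duplication import (
    classify_tandem,
    detect_duplicates,
    find_hotspots,
    write_hotspots_bed,
)
from .expression import (
    call_degs,
    compute_fpkm,
    deg_fraction_text,
    degs_to_frame,
    expression_heat_table,
    filter_expressed,
)
from .families import (
    FamilyReference,
    assign_family,
    count_table,
    load_reference_count_table,
)
from .models import FAMILIES, UNASSIGNED, SeqEntry
from .motifs import frequency_matrix, load_default_motifs, scan_motifs
from .phenotype import height_lignin_correlation
from .phylogeny import MSA, bootstrap_support, classify_family, write_newick
from .synthetic import StudyConfig, generate_study

STAGES = (
    "make-study", "families", "duplicates", "hotspots",
    "trees", "degs", "phenotype", "motifs",
)


@dataclass
class PipelineConfig:
    study_dir: Path
    out_dir: Path
    seed: int = 1
    # thresholds, pinned to the reference cut-offs
    identity_threshold: float = 0.80
    coverage_threshold: float = 0.80
    hotspot_min_genes: int = 5
    hotspot_window_bp: int = 5_000_000
    tandem_max_separation_bp: int = 100_000
    min_fpkm: float = 1.0
    fc_threshold: float = 2.0
    fdr: float = 0.05
    promoter_length: int = 2000
    bootstrap_reps: int = 1000
    min_align_score: float = 100.0
    correlation_mode: str = "genotype_means"
    # duplicate search restricted to same-family gene pairs (the catalogue
    # is family-structured; cross-family pairs cannot satisfy 80/80)
    within_family_duplicates: bool = True
    synthetic: bool = False
    study: StudyConfig = field(default_factory=StudyConfig)

    def validate(self) -> None:
        if not (0 < self.identity_threshold < 1 and 0 < self.coverage_threshold < 1):
            raise ValueError("identity/coverage thresholds must be in (0, 1)")
        if self.hotspot_min_genes < 2 or self.hotspot_window_bp <= 0:
            raise ValueError("bad hotspot parameters")
        if not (0 < self.fdr < 1) or self.fc_threshold < 1:
            raise ValueError("bad DEG parameters")
        if self.bootstrap_reps < 1 or self.promoter_length <= 0:
            raise ValueError("bad bootstrap/promoter parameters")

    def to_dict(self) -> dict:
        """Parameter dict for hashing/reporting; paths are excluded so the
        manifest depends only on the analysis parameters, not on where the
        run happens to live."""
        d = dataclasses.asdict(self)
        d.pop("study_dir")
        d.pop("out_dir")
        d["study"] = {
            k: v for k, v in dataclasses.asdict(self.study).items()
            if not isinstance(v, tuple)
        }
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(cfg: PipelineConfig, stage: str, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
    }
    out = cfg.out_dir / f"manifest_{stage.replace('-', '_')}.json"
    tmp = out.with_suffix(".tmp")
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    tmp.rename(out)


def _need(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def _load_refs(study: Path) -> list[FamilyReference]:
    members = mio.read_fasta(_need(study / "family_refs.faa"), alphabet="protein")
    motif_df = pd.read_csv(_need(study / "required_motifs.tsv"), sep="\t")
    by_family: dict[str, list[SeqEntry]] = {}
    for m in members:
        fam = m.id.rsplit("_ref", 1)[0]
        by_family.setdefault(fam, []).append(m)
    refs = []
    for fam, mem in by_family.items():
        motifs = tuple(motif_df.loc[motif_df.family == fam, "motif"])
        refs.append(
            FamilyReference(family=fam, members=tuple(mem), required_motifs=motifs)
        )
    return sorted(refs, key=lambda r: r.family)


# ---------------------------------------------------------------------------
# stages


def stage_make_study(cfg: PipelineConfig) -> dict:
    truth = generate_study(cfg.seed, cfg.study_dir, cfg.study)
    return {
        "n_genes": len(truth.family_of),
        "n_planted_duplicate_pairs": len(truth.planted_duplicate_pairs),
        "n_planted_hotspots": len(truth.planted_hotspots),
        "n_planted_degs": len(truth.planted_deg_ids),
    }


def stage_families(cfg: PipelineConfig) -> dict:
    study, out = cfg.study_dir, cfg.out_dir
    records = mio.read_gff3(_need(study / "genome.gff3"))
    proteins = mio.read_fasta(_need(study / "proteins.faa"), alphabet="protein")
    refs = _load_refs(study)
    assigned = {
        p.id: assign_family(p, refs, min_score=cfg.min_align_score)
        for p in proteins
    }
    annotated = {r.gene_id: r.family for r in records}
    n_match = sum(
        assigned.get(g) == fam for g, fam in annotated.items() if fam != UNASSIGNED
    )
    with open(out / "family_assignments.tsv", "w") as fh:
        fh.write("gene_id\tassigned_family\tannotated_family\n")
        for gid in sorted(assigned):
            fh.write(f"{gid}\t{assigned[gid]}\t{annotated.get(gid, UNASSIGNED)}\n")
    reassigned = [
        dataclasses.replace(r, family=assigned[r.gene_id])
        for r in records
        if assigned.get(r.gene_id, UNASSIGNED) != UNASSIGNED
    ]
    sub_table = count_table(reassigned, group_by="subgenome")
    sub_table.to_csv(out / "family_counts_subgenome.tsv", sep="\t")
    ref_table = load_reference_count_table()
    ref_table.to_csv(out / "family_counts_reference.tsv", sep="\t")
    _write_manifest(cfg, "families", [study / "genome.gff3", study / "proteins.faa"])
    return {
        "n_genes": len(records),
        "n_assigned": len(reassigned),
        "assignment_recovery": n_match / max(len(annotated), 1),
        "subgenome_totals": sub_table["Total"].to_dict(),
        "reference_totals": ref_table["Total"].to_dict(),
    }


def stage_duplicates(cfg: PipelineConfig) -> dict:
    study, out = cfg.study_dir, cfg.out_dir
    records = mio.read_gff3(_need(study / "genome.gff3"))
    cds = {e.id: e for e in mio.read_fasta(_need(study / "cds.fna"))}
    if cfg.within_family_duplicates:
        groups: dict[str, list] = {}
        for r in records:
            if r.family != UNASSIGNED:
                groups.setdefault(r.family, []).append(r)
        pairs = []
        for fam in sorted(groups):
            pairs.extend(
                detect_duplicates(
                    groups[fam], cds,
                    identity_threshold=cfg.identity_threshold,
                    coverage_threshold=cfg.coverage_threshold,
                )
            )
        pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    else:
        pairs = detect_duplicates(
            records, cds,
            identity_threshold=cfg.identity_threshold,
            coverage_threshold=cfg.coverage_threshold,
        )
    pairs = classify_tandem(pairs, records, cfg.tandem_max_separation_bp)
    with open(out / "duplicate_pairs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tidentity\tcoverage_longer\ttandem\n")
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.identity:.6f}"
                f"\t{p.coverage_longer:.6f}\t{str(p.tandem).lower()}\n"
            )
    _write_manifest(cfg, "duplicates", [study / "genome.gff3", study / "cds.fna"])
    return {
        "n_pairs": len(pairs),
        "n_tandem": sum(p.tandem for p in pairs),
        "pairs": [[p.gene_a, p.gene_b] for p in pairs],
    }


def stage_hotspots(cfg: PipelineConfig) -> dict:
    study, out = cfg.study_dir, cfg.out_dir
    records = mio.read_gff3(_need(study / "genome.gff3"))
    hotspots = find_hotspots(
        records, min_genes=cfg.hotspot_min_genes, window_bp=cfg.hotspot_window_bp
    )
    with open(out / "hotspots.tsv", "w") as fh:
        fh.write("chromosome\tstart\tend\tn_genes\tmember_gene_ids\n")
        for h in hotspots:
            fh.write(
                f"{h.chromosome}\t{h.start}\t{h.end}\t{len(h.member_gene_ids)}"
                f"\t{','.join(h.member_gene_ids)}\n"
            )
    write_hotspots_bed(hotspots, out / "hotspots.bed")
    _write_manifest(cfg, "hotspots", [study / "genome.gff3"])
    return {
        "n_hotspots": len(hotspots),
        "hotspots": [[h.chromosome, h.start, h.end] for h in hotspots],
    }


def stage_trees(cfg: PipelineConfig) -> dict:
    study, out = cfg.study_dir, cfg.out_dir
    groups_df = pd.read_csv(_need(study / "taxon_groups.tsv"), sep="\t")
    group_of_taxon = dict(zip(groups_df.taxon, groups_df.group))
    classes = {}
    for family in FAMILIES:
        path = study / f"msa_{family}.faa"
        if not path.exists():
            continue
        entries = mio.read_fasta(path, alphabet="protein")
        group_of = {
            e.id: group_of_taxon[e.id.split("_", 1)[1]] for e in entries
        }
        msa = MSA(
            ids=[e.id for e in entries],
            rows=[e.residues for e in entries],
            group_of=group_of,
        )
        tree, _support = bootstrap_support(
            msa, n_reps=cfg.bootstrap_reps, seed=cfg.seed
        )
        write_newick(tree, out / f"tree_{family}.nwk")
        classes[family] = classify_family(tree, group_of)
    with open(out / "family_classes.tsv", "w") as fh:
        fh.write("family\tclass\n")
        for family in FAMILIES:
            if family in classes:
                fh.write(f"{family}\t{classes[family]}\n")
    _write_manifest(cfg, "trees", [study / "taxon_groups.tsv"])
    return {"classes": classes}


def stage_degs(cfg: PipelineConfig) -> dict:
    study, out = cfg.study_dir, cfg.out_dir
    samples = mio.read_sample_sheet(_need(study / "samples.tsv"))
    counts = mio.read_counts(_need(study / "counts.tsv"), samples)
    lengths = pd.read_csv(
        _need(study / "gene_lengths.tsv"), sep="\t", index_col=0
    )["length_bp"]
    matrix = compute_fpkm(counts, lengths, samples)
    expressed = filter_expressed(matrix, min_fpkm=cfg.min_fpkm)
    results = call_degs(
        matrix, fc_threshold=cfg.fc_threshold, fdr=cfg.fdr, genes=expressed
    )
    frame = degs_to_frame(results)
    frame.to_csv(out / "deg_report.tsv", sep="\t", index=False, float_format="%.6g")
    heat = expression_heat_table(matrix).loc[expressed]
    heat.to_csv(out / "heat_table.tsv", sep="\t", float_format="%.4f")
    n_deg = int(frame.is_deg.sum())
    _write_manifest(
        cfg, "degs",
        [study / "samples.tsv", study / "counts.tsv", study / "gene_lengths.tsv"],
    )
    return {
        "n_genes": int(counts.shape[0]),
        "n_expressed": len(expressed),
        "n_deg": n_deg,
        "deg_fraction": deg_fraction_text(n_deg, len(expressed)) if expressed else "0%",
        "deg_ids": sorted(frame.loc[frame.is_deg, "gene_id"]),
        "n_up_in_short": int((frame.is_deg & (frame.direction == "up_in_short")).sum()),
        "n_up_in_tall": int((frame.is_deg & (frame.direction == "up_in_tall")).sum()),
    }


def stage_phenotype(cfg: PipelineConfig) -> dict:
    study, out = cfg.study_dir, cfg.out_dir
    records = mio.read_phenotypes(_need(study / "phenotypes.tsv"))
    report = height_lignin_correlation(records, mode=cfg.correlation_mode)
    with open(out / "phenotype_stats.tsv", "w") as fh:
        fh.write("r\tp_value\tn\tmode\n")
        fh.write(f"{report.r:.6f}\t{report.p_value:.6f}\t{report.n}\t{report.mode}\n")
    _write_manifest(cfg, "phenotype", [study / "phenotypes.tsv"])
    return {"r": report.r, "p_value": report.p_value, "n": report.n}


def stage_motifs(cfg: PipelineConfig) -> dict:
    study, out = cfg.study_dir, cfg.out_dir
    promoters = mio.read_fasta(_need(study / "promoters.fna"))
    vocab = load_default_motifs(
        study / "motifs.tsv" if (study / "motifs.tsv").exists() else None
    )
    motif_list = list(vocab.iupac)
    records = mio.read_gff3(_need(study / "genome.gff3"))
    family_of = {r.gene_id: r.family for r in records}
    gene_ids = [r.gene_id for r in records]
    hits = []
    for prom in promoters:
        hits.extend(scan_motifs(prom, motif_list))
    with open(out / "motif_hits.tsv", "w") as fh:
        fh.write("gene_id\tmotif\toffset\tstrand\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.motif}\t{h.offset}\t{h.strand}\n")
    gene_matrix = frequency_matrix(hits, grouping="gene", gene_ids=gene_ids)
    gene_matrix.to_csv(out / "motif_matrix_gene.tsv", sep="\t")
    family_matrix = frequency_matrix(
        hits, grouping="family", gene_ids=gene_ids, family_of=family_of
    )
    family_matrix.to_csv(out / "motif_matrix_family.tsv", sep="\t")
    summary = {"n_hits": len(hits), "n_motifs": len(motif_list)}
    xylem_path = study / "xylem_genes.txt"
    if xylem_path.exists():
        xylem = [l.strip() for l in xylem_path.read_text().splitlines() if l.strip()]
        xylem_matrix = frequency_matrix(
            hits, grouping="gene", gene_ids=gene_ids, subset=xylem
        )
        xylem_matrix.to_csv(out / "motif_matrix_xylem.tsv", sep="\t")
        summary["n_xylem_genes"] = len(xylem)
    _write_manifest(cfg, "motifs", [study / "promoters.fna", study / "genome.gff3"])
    return summary


_STAGE_FN = {
    "make-study": stage_make_study,
    "families": stage_families,
    "duplicates": stage_duplicates,
    "hotspots": stage_hotspots,
    "trees": stage_trees,
    "degs": stage_degs,
    "phenotype": stage_phenotype,
    "motifs": stage_motifs,
}


def run_stage(stage: str, cfg: PipelineConfig) -> dict:
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    cfg.validate()
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FN[stage](cfg)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write one summary.json."""
    cfg.validate()
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "thresholds": {
        "identity": cfg.identity_threshold,
        "coverage": cfg.coverage_threshold,
        "hotspot_min_genes": cfg.hotspot_min_genes,
        "hotspot_window_bp": cfg.hotspot_window_bp,
        "min_fpkm": cfg.min_fpkm,
        "fc_threshold": cfg.fc_threshold,
        "fdr": cfg.fdr,
        "promoter_length": cfg.promoter_length,
        "bootstrap_reps": cfg.bootstrap_reps,
    }}
    if cfg.synthetic:
        summary["make-study"] = stage_make_study(cfg)
    for stage in STAGES[1:]:
        summary[stage] = _STAGE_FN[stage](cfg)

    truth_path = cfg.study_dir / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        detected_pairs = {tuple(p) for p in summary["duplicates"]["pairs"]}
        planted_pairs = {tuple(p) for p in truth["planted_duplicate_pairs"]}
        detected_deg = set(summary["degs"]["deg_ids"])
        planted_deg = set(truth["planted_deg_ids"])
        detected_hs = {
            (c, s, e) for c, s, e in map(tuple, summary["hotspots"]["hotspots"])
        }
        planted_hs = {(c, s, e) for c, s, e in map(tuple, truth["planted_hotspots"])}
        classes = summary["trees"]["classes"]
        detected_hits = set()
        hits_path = cfg.out_dir / "motif_hits.tsv"
        for line in hits_path.read_text().splitlines()[1:]:
            gene, motif, offset, strand = line.split("\t")
            detected_hits.add((gene, motif, int(offset), strand))
        planted_hits = {
            (g, m, int(o), s) for g, m, o, s in map(tuple, truth["planted_motif_hits"])
        }
        summary["recovery"] = {
            "motif_hits": _rate(planted_hits, detected_hits),
            "duplicate_pairs": _rate(planted_pairs, detected_pairs),
            "hotspots": _rate(planted_hs, detected_hs),
            "deg_sensitivity": _rate(planted_deg, detected_deg),
            "deg_false_discoveries": len(detected_deg - planted_deg),
            "family_classes": _rate(
                set(truth["family_classes"].items()), set(classes.items())
            ),
        }
    out = cfg.out_dir / "summary.json"
    tmp = out.with_suffix(".tmp")
    tmp.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    tmp.rename(out)
    return summary


def _rate(planted: set, detected: set) -> float:
    if not planted:
        return 1.0
    return len(planted & detected) / len(planted)
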