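"""Strict 80/80 duplicate detection, tandem classification, hotspots."""

import numpy as np
import pytest

from monolignol.duplication import (
    DuplicationPair,
    classify_tandem,
    detect_duplicates,
    find_hotspots,
)
from monolignol.models import GeneRecord, SeqEntry
from monolignol.synthetic import (
    DuplicateSpec,
    StudyConfig,
    engineer_duplicate_pair,
    generate_genome,
)

from conftest import dna_entry, hotspot_oracle, random_dna, sw_score_oracle


def _recs(*specs):
    return [
        GeneRecord(gid, chrom, start, end, family="PAL")
        for gid, chrom, start, end in specs
    ]


class TestDetectDuplicates:
    def test_identical_pair_kept(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 1000)
        records = _recs(("g1", "chrA01", 1, 1000), ("g2", "chrA02", 1, 1000))
        cds = {"g1": dna_entry("g1", seq), "g2": dna_entry("g2", seq)}
        (pair,) = detect_duplicates(records, cds)
        assert (pair.identity, pair.coverage_longer) == (1.0, 1.0)
        assert (pair.gene_a, pair.gene_b) == ("g1", "g2")

    def test_boundary_identity_exactly_080_rejected(self):
        """The rule is strict: identity exactly 0.80 does not qualify."""
        a, b = engineer_duplicate_pair(5, length=600, identity=0.80)
        records = _recs(("pa", "chrA01", 1, 600), ("pb", "chrA02", 1, 600))
        cds = {"pa": dna_entry("pa", a.residues), "pb": dna_entry("pb", b.residues)}
        assert detect_duplicates(records, cds) == []
        # ... but it is the threshold that rejects it, not the alignment
        assert detect_duplicates(records, cds, identity_threshold=0.79)

    def test_missing_sequence_names_gene(self):
        records = _recs(("g1", "chrA01", 1, 100))
        with pytest.raises(ValueError, match="g1"):
            detect_duplicates(records, {})

    def test_threshold_monotonicity_and_order_invariance(self):
        cfg = StudyConfig(
            genes_per_family=2, n_unplaced=2, cds_len=400,
            hotspots=(),
            duplicates=(
                DuplicateSpec(0.85, 1.0, tandem=True),
                DuplicateSpec(0.95, 0.9, tandem=False),
            ),
        )
        genome = generate_genome(2, cfg)
        cds = {e.id: e for e in genome.cds}
        strict = detect_duplicates(genome.records, cds)
        loose = detect_duplicates(genome.records, cds, identity_threshold=0.5,
                                  coverage_threshold=0.5)
        assert {(p.gene_a, p.gene_b) for p in strict} <= {
            (p.gene_a, p.gene_b) for p in loose
        }
        shuffled = detect_duplicates(list(reversed(genome.records)), cds)
        assert strict == shuffled

    def test_matches_brute_force_oracle_and_ground_truth(self):
        """On a small catalogue the detected set equals both the planted
        pairs and an independent all-pairs Smith-Waterman oracle."""
        cfg = StudyConfig(
            genes_per_family=1, n_unplaced=2, cds_len=300,
            hotspots=(),
            duplicates=(
                DuplicateSpec(0.95, 1.0, tandem=True),
                DuplicateSpec(0.85, 1.0, tandem=False),
            ),
        )
        genome = generate_genome(8, cfg)
        cds = {e.id: e for e in genome.cds}
        detected = {
            (p.gene_a, p.gene_b) for p in detect_duplicates(genome.records, cds)
        }
        assert detected == genome.truth.planted_duplicate_pairs

        ids = sorted(cds)
        oracle = set()
        for i, ga in enumerate(ids):
            for gb in ids[i + 1:]:
                _score, ident, cov = sw_score_oracle(
                    cds[ga].residues, cds[gb].residues
                )
                if ident > 0.80 and cov > 0.80:
                    oracle.add((ga, gb))
        assert detected == oracle


class TestClassifyTandem:
    def test_same_chromosome_within_cutoff(self):
        records = _recs(("g1", "chrA11", 1, 1000), ("g2", "chrA11", 21_000, 22_000))
        pairs = [DuplicationPair("g1", "g2", 0.9, 0.9)]
        (out,) = classify_tandem(pairs, records)
        assert out.tandem

    def test_different_chromosomes_not_tandem(self):
        records = _recs(("g1", "chrA01", 1, 1000), ("g2", "chrB01", 1, 1000))
        (out,) = classify_tandem([DuplicationPair("g1", "g2", 0.9, 0.9)], records)
        assert not out.tandem

    def test_planted_tandem_pairs_recovered(self):
        cfg = StudyConfig(
            genes_per_family=2, n_unplaced=2, cds_len=400, hotspots=(),
            duplicates=(
                DuplicateSpec(0.90, 1.0, tandem=True),
                DuplicateSpec(0.90, 1.0, tandem=False),
            ),
        )
        genome = generate_genome(4, cfg)
        cds = {e.id: e for e in genome.cds}
        pairs = classify_tandem(
            detect_duplicates(genome.records, cds), genome.records
        )
        tandem = {(p.gene_a, p.gene_b) for p in pairs if p.tandem}
        assert tandem == genome.truth.planted_tandem_pairs


def _placed(positions, chrom="chrA01", size=1000):
    return [
        GeneRecord(f"g{k:03d}", chrom, int(s), int(s) + size - 1, family="PAL")
        for k, s in enumerate(sorted(positions))
    ]


class TestFindHotspots:
    def test_five_genes_under_window(self):
        recs = _placed([1, 1_000_001, 2_000_001, 3_000_001, 4_000_001])
        (hs,) = find_hotspots(recs)
        assert hs.member_gene_ids == tuple(r.gene_id for r in recs)
        assert hs.end - hs.start + 1 < 5_000_000

    def test_exact_window_span_rejected(self):
        # span exactly 5.0 Mb: strict "<" means no hotspot
        recs = _placed([1, 1_000_001, 2_000_001, 3_000_001, 4_999_001])
        assert recs[-1].end - recs[0].start + 1 == 5_000_000
        assert find_hotspots(recs) == []

    def test_unassigned_genes_ignored(self):
        recs = _placed([1, 1_000_001, 2_000_001, 3_000_001, 4_000_001])
        recs[2] = GeneRecord("g002", "chrA01", 2_000_001, 2_001_000)  # unassigned
        assert find_hotspots(recs) == []

    def test_matches_subinterval_oracle_on_random_layouts(self):
        """Reported hotspots equal the brute-force enumeration of maximal
        qualifying subintervals on 100 random gene layouts."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(3, 25))
            starts = sorted(int(s) for s in rng.integers(1, 30_000_000, size=n))
            recs = _placed(starts)
            expected = hotspot_oracle(
                [(r.start, r.end) for r in recs]
            )
            got = find_hotspots(recs)
            assert len(got) == len(expected)
            for hs, (i, j) in zip(got, sorted(expected)):
                assert hs.member_gene_ids == tuple(
                    r.gene_id for r in recs[i : j + 1]
                )

    def test_planted_hotspots_recovered_exactly(self):
        from monolignol.synthetic import HotspotSpec

        cfg = StudyConfig(
            genes_per_family=3, n_unplaced=3, cds_len=300,
            hotspots=(
                HotspotSpec("chrA01", 6, 3_000_000),
                HotspotSpec("chrB16", 5, 2_000_000),
            ),
            duplicates=(),
        )
        genome = generate_genome(21, cfg)
        detected = {
            (h.chromosome, h.start, h.end) for h in find_hotspots(genome.records)
        }
        assert detected == set(genome.truth.planted_hotspots)
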