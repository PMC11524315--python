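"""FPKM normalization, the expression filter and the DEG decision rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from monolignol.expression import (
    bh_adjust,
    call_degs,
    compute_fpkm,
    deg_fraction_text,
    expression_heat_table,
    filter_expressed,
)
from monolignol.models import SampleInfo
from monolignol.synthetic import generate_counts, make_samples

from conftest import bh_oracle

SAMPLES = [
    SampleInfo("T_1", "T", 1, "tall"),
    SampleInfo("T_2", "T", 2, "tall"),
    SampleInfo("T_3", "T", 3, "tall"),
    SampleInfo("S_1", "S", 1, "short"),
    SampleInfo("S_2", "S", 2, "short"),
    SampleInfo("S_3", "S", 3, "short"),
]


def _matrix(counts, lengths, samples=SAMPLES):
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"g{i}" for i in range(len(counts))], name="gene_id"),
        columns=[s.sample_id for s in samples],
    )
    lengths = pd.Series(lengths, index=df.index)
    return compute_fpkm(df, lengths, samples)


class TestFPKM:
    def test_textbook_value(self):
        # count 10, length 1000 bp, library 1e6 -> FPKM 10
        two = [SampleInfo("A_1", "A", 1, "tall"), SampleInfo("B_1", "B", 1, "short")]
        counts = pd.DataFrame(
            {"A_1": [10, 10**6 - 10], "B_1": [10, 10**6 - 10]},
            index=pd.Index(["g0", "filler"], name="gene_id"),
        )
        lengths = pd.Series([1000, 10**6], index=counts.index)
        m = compute_fpkm(counts, lengths, two)
        assert m.fpkm.loc["g0", "A_1"] == pytest.approx(10.0)

    def test_all_zero_gene_stays_zero(self):
        m = _matrix([[0] * 6, [5] * 6], [1000, 1000])
        assert (m.fpkm.loc["g0"] == 0).all()

    def test_scale_invariance_within_sample(self):
        counts = np.array([[10, 20], [30, 40]])
        two = [SampleInfo("A_1", "A", 1, "tall"), SampleInfo("B_1", "B", 1, "short")]
        m1 = _matrix(counts, [500, 800], two)
        m2 = _matrix(counts * np.array([3, 1]), [500, 800], two)
        assert np.allclose(m1.fpkm.to_numpy(), m2.fpkm.to_numpy())

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            _matrix([[0] * 6], [1000])


class TestFilterExpressed:
    def test_boundary_value_is_dropped(self):
        # FPKM exactly 1.0 everywhere -> strictly-greater filter drops it
        m = _matrix([[1, 1, 1, 1, 1, 1], [10**6 - 1] * 6], [1000, 10**9])
        assert np.allclose(m.fpkm.loc["g0"], 1.0)
        assert filter_expressed(m) == []

    def test_single_high_replicate_keeps_gene(self):
        m = _matrix([[15, 0, 0, 0, 0, 0], [10**6 - 15] * 6], [1000, 10**9])
        assert "g0" in filter_expressed(m)

    def test_idempotent(self):
        m = _matrix([[50] * 6, [0] * 6, [7] * 6], [1000, 1000, 1000])
        kept = filter_expressed(m)
        assert filter_expressed(m) == kept


class TestBH:
    def test_stepup_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_definition_on_grid(self):
        """q-values equal the step-up definition: exhaustively for short
        vectors on the 0.05 grid, sampled for lengths up to 8."""
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
        for m in (1, 2, 3):
            for p in itertools.product(grid, repeat=m):
                assert np.allclose(bh_adjust(list(p)), bh_oracle(p)), p
        rng = np.random.default_rng(5)
        for _ in range(500):
            m = int(rng.integers(4, 9))
            p = grid[rng.integers(0, len(grid), size=m)]
            assert np.allclose(bh_adjust(p), bh_oracle(p)), p


class TestCallDegs:
    def test_identical_groups_yield_no_degs(self):
        m = _matrix([[40] * 6, [7] * 6], [1000, 1000])
        results = call_degs(m)
        assert not any(r.is_deg for r in results)

    def test_requires_two_samples_per_group(self):
        samples = [SampleInfo("T_1", "T", 1, "tall"),
                   SampleInfo("S_1", "S", 1, "short"),
                   SampleInfo("S_2", "S", 2, "short")]
        m = _matrix([[10, 10, 10], [20, 20, 20]], [1000, 1000], samples)
        with pytest.raises(ValueError, match="2 samples"):
            call_degs(m)

    def test_direction_follows_fold_change(self):
        # filler gene keeps library sizes comparable across samples
        m = _matrix(
            [[400, 380, 420, 50, 55, 45], [10**6] * 6], [1000, 1000]
        )
        result = {r.gene_id: r for r in call_degs(m)}
        assert result["g0"].log2fc > 1
        assert result["g0"].direction == "up_in_tall"

    def test_null_simulation_controls_false_discoveries(self):
        """With no planted effects the rate of q < 0.05 calls stays at or
        below the nominal level (200 genes x 50 replicate simulations)."""
        samples = make_samples()
        genes = [f"g{i:03d}" for i in range(200)]
        total = false = 0
        for rep in range(50):
            counts = generate_counts(
                1000 + rep, genes, samples, planted_degs={},
                nb_dispersion=0.05, base_mean=500.0,
            )
            lengths = pd.Series(1000, index=counts.index)
            m = compute_fpkm(counts, lengths, samples)
            for r in call_degs(m):
                total += 1
                false += r.q_value < 0.05
        assert false / total <= 0.05

    def test_planted_effects_recovered(self):
        """Planted 4-fold effects at base mean 500, dispersion 0.05 are
        recovered with >= 90% sensitivity."""
        samples = make_samples()
        genes = [f"g{i:03d}" for i in range(200)]
        planted = {g: (2.0 if i % 2 else -2.0) for i, g in enumerate(genes[:40])}
        counts = generate_counts(
            77, genes, samples, planted_degs=planted,
            nb_dispersion=0.05, base_mean=500.0,
        )
        lengths = pd.Series(1000, index=counts.index)
        m = compute_fpkm(counts, lengths, samples)
        deg_ids = {r.gene_id for r in call_degs(m) if r.is_deg}
        assert len(deg_ids & set(planted)) / len(planted) >= 0.90


class TestHeatTable:
    @pytest.mark.parametrize("fpkm,expected", [(0, 0.0), (1, 1.0), (7, 3.0)])
    def test_log_transform_values(self, fpkm, expected):
        two = [SampleInfo("A_1", "A", 1, "tall"), SampleInfo("B_1", "B", 1, "short")]
        counts = pd.DataFrame(
            {"A_1": [fpkm, 1000], "B_1": [fpkm, 1000]},
            index=pd.Index(["g0", "filler"], name="gene_id"),
        )
        lib = counts.sum()["A_1"]
        lengths = pd.Series([int(1e9 / lib), int(1e9 / lib)], index=counts.index)
        m = compute_fpkm(counts, lengths, two)
        assert expression_heat_table(m).loc["g0", "A_1"] == pytest.approx(
            expected, abs=1e-4
        )


def test_deg_fraction_formatting():
    assert deg_fraction_text(23, 117) == "19.66%"
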