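import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chipquant import (
    CalibrationTable,
    GenomeModel,
    GeneRecord,
    SubtractionParams,
    SyntheticSpec,
    apply_global_calibration,
    compute_coverage,
    gene_body_signal,
    make_genome,
    ratio_profile,
    scale_to_unit_mean,
    simulate_chip_reads,
    simulate_input_reads,
    subtract_input,
    tss_profile,
)
from chipquant.model import GenePartition, SignalTrack

from conftest import make_track, poisson_upper_quantile_oracle


def brute_force_coverage(reads, chrom_sizes, bin_size):
    """Per-base loop oracle for binned coverage."""
    out = {}
    for chrom, size in chrom_sizes.items():
        per_base = np.zeros(size)
        for _, r in reads[reads["chrom"] == chrom].iterrows():
            for pos in range(r["start"], min(r["end"], size)):
                per_base[pos] += 1
        n_bins = -(-size // bin_size)
        vals = np.zeros(n_bins)
        for b in range(n_bins):
            vals[b] = per_base[b * bin_size:(b + 1) * bin_size].sum() / bin_size
        out[chrom] = vals
    return out


class TestComputeCoverage:
    def test_read_inside_one_bin(self, tiny_genome):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [300]})
        t = compute_coverage(reads, tiny_genome, bin_size=200)
        assert t.values["chr1"][1] == pytest.approx(0.5)
        assert t.values["chr1"].sum() == pytest.approx(0.5)

    def test_read_straddling_two_bins(self, tiny_genome):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [140], "end": [240]})
        t = compute_coverage(reads, tiny_genome, bin_size=100)
        assert t.values["chr1"][1] == pytest.approx(0.6)
        assert t.values["chr1"][2] == pytest.approx(0.4)

    def test_matches_per_base_oracle(self, tiny_genome):
        rng = np.random.default_rng(0)
        n = 200
        chroms = rng.choice(["chr1", "chr2"], size=n)
        sizes = np.array([tiny_genome.chrom_sizes[c] for c in chroms])
        starts = rng.integers(0, sizes - 80)
        reads = pd.DataFrame({"chrom": chroms, "start": starts,
                              "end": starts + rng.integers(20, 80, size=n)})
        t = compute_coverage(reads, tiny_genome, bin_size=130)
        oracle = brute_force_coverage(reads, tiny_genome.chrom_sizes, 130)
        for c in tiny_genome.chrom_sizes:
            np.testing.assert_allclose(t.values[c], oracle[c], atol=1e-12)

    def test_resolution_consistency(self, tiny_genome):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 9_900, size=100)
        reads = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 50})
        fine = compute_coverage(reads, tiny_genome, bin_size=1)
        coarse = compute_coverage(reads, tiny_genome, bin_size=100)
        agg = fine.values["chr1"].reshape(-1, 100).mean(axis=1)
        np.testing.assert_allclose(agg, coarse.values["chr1"], atol=1e-12)


class TestScaleToUnitMean:
    def test_equal_bins_example(self):
        t = make_track({"chr1": [2.0, 4.0, 6.0]})
        np.testing.assert_allclose(scale_to_unit_mean(t).values["chr1"],
                                   [0.5, 1.0, 1.5])

    def test_idempotent_on_unit_mean_track(self):
        t = make_track({"chr1": [0.5, 1.0, 1.5]})
        np.testing.assert_allclose(scale_to_unit_mean(t).values["chr1"],
                                   t.values["chr1"])

    def test_all_zero_track_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            scale_to_unit_mean(make_track({"chr1": [0.0, 0.0]}))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=2,
                    max_size=50).filter(lambda v: sum(v) > 0))
    def test_unit_mean_invariant_and_order_preserved(self, vals):
        t = make_track({"chr1": vals})
        out = scale_to_unit_mean(t)
        assert out.mean() == pytest.approx(1.0, abs=1e-9)
        assert list(np.argsort(out.values["chr1"], kind="stable")) == list(
            np.argsort(t.values["chr1"], kind="stable"))


class TestSubtractInput:
    def test_worked_example_in_read_units(self):
        # chip = 10 reads, lambda = 2, p_upper = 0.001 -> quantile 8, residue 2
        chip = make_track({"chr1": [10.0]})
        inp = make_track({"chr1": [2.0]})
        out = subtract_input(chip, inp, SubtractionParams(p_upper=0.001),
                             chip_depth=1.0)
        assert poisson_upper_quantile_oracle(2.0, 0.001) == 8
        assert out.values["chr1"][0] == pytest.approx(2.0)

    def test_zero_lambda_leaves_chip_unchanged(self):
        chip = make_track({"chr1": [3.0, 7.0]})
        inp = make_track({"chr1": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="all zero"):
            out = subtract_input(chip, inp, chip_depth=5.0)
        np.testing.assert_array_equal(out.values["chr1"], chip.values["chr1"])

    def test_floored_at_zero(self):
        chip = make_track({"chr1": [1.0]})
        inp = make_track({"chr1": [5.0]})
        out = subtract_input(chip, inp, chip_depth=1.0)
        assert out.values["chr1"][0] == 0.0

    def test_mismatched_grids_rejected(self):
        chip = make_track({"chr1": [1.0, 2.0]})
        inp = make_track({"chr1": [1.0]})
        with pytest.raises(ValueError, match="grid"):
            subtract_input(chip, inp, chip_depth=1.0)

    def test_negative_values_rejected(self):
        chip = make_track({"chr1": [-1.0]})
        inp = make_track({"chr1": [1.0]})
        with pytest.raises(ValueError, match="negative"):
            subtract_input(chip, inp, chip_depth=1.0)

    def test_matches_enumerated_poisson_oracle(self):
        # exhaustive per-bin CDF enumeration on a 1e4-bin fixture, exact match
        rng = np.random.default_rng(42)
        n = 10_000
        chip_v = rng.uniform(0, 20, size=n)
        inp_v = rng.uniform(0, 4, size=n)
        inp_v[:100] = 0.0
        depth = 6.5
        chip = make_track({"chr1": chip_v})
        inp = make_track({"chr1": inp_v})
        params = SubtractionParams(p_upper=0.001)
        out = subtract_input(chip, inp, params, chip_depth=depth)
        expected = np.array([
            max(c - poisson_upper_quantile_oracle(l * depth, params.p_upper) / depth,
                0.0)
            for c, l in zip(chip_v, inp_v)
        ])
        np.testing.assert_array_equal(out.values["chr1"], expected)


class TestCalibration:
    def _calib(self):
        return CalibrationTable(pd.DataFrame({
            "sample_id": ["ctrl", "mut"], "mark": ["me2", "me2"],
            "global_level": [1.0, 0.4]}))

    def test_level_scales_mean(self):
        t = make_track({"chr1": [0.5, 1.0, 1.5]}, sample_id="mut", mark="me2")
        out = apply_global_calibration(t, self._calib())
        assert out.mean() == pytest.approx(0.4)

    def test_reference_sample_unchanged(self):
        t = make_track({"chr1": [0.5, 1.5]}, sample_id="ctrl", mark="me2")
        np.testing.assert_array_equal(
            apply_global_calibration(t, self._calib()).values["chr1"],
            t.values["chr1"])

    def test_missing_calibration_row_rejected(self):
        t = make_track({"chr1": [1.0]}, sample_id="other", mark="me2")
        with pytest.raises(KeyError):
            apply_global_calibration(t, self._calib())

    @pytest.mark.parametrize("g", [0.3, 0.5, 1.0])
    def test_planted_depletion_recovered_only_with_calibration(self, g):
        spec = SyntheticSpec(seed=13, n_chroms=1, chrom_length=2_000_000,
                             n_genes=20, global_depletion=g, background_rate=5.0)
        genome = make_genome(spec)
        calib = CalibrationTable(pd.DataFrame({
            "sample_id": ["WT_s", "MUT_s"], "mark": ["H3K36me2"] * 2,
            "global_level": [1.0, g]}))
        totals = {}
        for cond, sid in (("WT", "WT_s"), ("MUT", "MUT_s")):
            reads, truth = simulate_chip_reads(genome, spec, "H3K36me2", cond)
            scaled = scale_to_unit_mean(
                compute_coverage(reads, genome, spec.bin_size)
            ).replace(sample_id=sid, mark="H3K36me2")
            totals[cond] = (scaled.total(),
                            apply_global_calibration(scaled, calib).total())
        uncal = totals["MUT"][0] / totals["WT"][0]
        cal = totals["MUT"][1] / totals["WT"][1]
        assert uncal == pytest.approx(1.0, abs=1e-9)
        assert cal == pytest.approx(g, abs=1e-9)


class TestGeneBodySignal:
    def test_constant_track(self, tiny_genome):
        t = make_track({"chr1": [3.0] * 100, "chr2": [3.0] * 80})
        gb = gene_body_signal(t, tiny_genome)
        assert all(v == pytest.approx(3.0) for v in gb)

    def test_single_bin_gene(self):
        genome = GenomeModel({"chr1": 1_000},
                             [GeneRecord("g", "chr1", "+", 100, 200, 100)])
        t = make_track({"chr1": np.arange(10, dtype=float)})
        assert gene_body_signal(t, genome)["g"] == pytest.approx(1.0)

    def test_matches_per_base_mean(self, tiny_genome):
        rng = np.random.default_rng(3)
        vals = {c: rng.uniform(0, 5, size=-(-s // 130))
                for c, s in tiny_genome.chrom_sizes.items()}
        t = make_track(vals, bin_size=130)
        gb = gene_body_signal(t, tiny_genome)
        for g in tiny_genome.genes:
            per_base = np.repeat(vals[g.chrom], 130)[g.start:g.end]
            assert gb[g.gene_id] == pytest.approx(per_base.mean())

    def test_gene_on_missing_chromosome_rejected(self, tiny_genome):
        t = make_track({"chr1": [1.0] * 100})
        with pytest.raises(ValueError, match="chr2"):
            gene_body_signal(t, tiny_genome)


class TestTssProfile:
    def test_constant_track_flat_curve(self, tiny_genome):
        t = make_track({"chr1": [2.0] * 100, "chr2": [2.0] * 80})
        _, curves = tss_profile(t, tiny_genome, window=500, step=100)
        np.testing.assert_allclose(curves["all"].values, 2.0)
        assert np.allclose(curves["all"].index, -curves["all"].index[::-1])

    def test_mirrored_strands_identical_rows(self):
        genome = GenomeModel(
            {"chr1": 10_000},
            [GeneRecord("plus", "chr1", "+", 3_000, 4_000, 1_000),
             GeneRecord("minus", "chr1", "-", 6_000, 7_001, 1_000)],
        )
        # mirrored signal: value at (7000 - d) equals value at (3000 + d)
        vals = np.zeros(10_000)
        rng = np.random.default_rng(6)
        vals[3_000 - 1_000:3_000 + 1_000] = rng.uniform(0, 5, size=2_000)
        for d in range(-1_000, 1_000):
            vals[7_000 - d] = vals[3_000 + d]
        t = make_track({"chr1": vals}, bin_size=1)
        pm, _ = tss_profile(t, genome, window=500, step=50)
        np.testing.assert_allclose(pm.matrix[0], pm.matrix[1])

    def test_planted_tss_enrichment_peaks_at_zero(self):
        spec = SyntheticSpec(seed=21, n_chroms=1, chrom_length=1_000_000,
                             n_genes=100, bin_size=100, tss_fold=6.0,
                             tss_halfwidth=100, enrichment_domains=())
        genome = make_genome(spec)
        reads, _ = simulate_chip_reads(genome, spec, "H3K36me2", "WT")
        track = scale_to_unit_mean(compute_coverage(reads, genome, 100))
        _, curves = tss_profile(track, genome, window=2_000, step=100)
        curve = curves["all"]
        peak_offset = curve.index[np.argmax(curve.values)]
        assert abs(peak_offset) <= 100  # within one profile bin of the TSS

    def test_window_not_multiple_of_step_rejected(self, tiny_genome):
        t = make_track({"chr1": [1.0] * 100, "chr2": [1.0] * 80})
        with pytest.raises(ValueError, match="multiple"):
            tss_profile(t, tiny_genome, window=500, step=130)

    def test_empty_group_named_in_error(self, tiny_genome):
        t = make_track({"chr1": [1.0] * 100, "chr2": [1.0] * 80})
        groups = GenePartition("grp", {"present": {"gA"}, "ghost": set()})
        with pytest.raises(ValueError, match="ghost"):
            tss_profile(t, tiny_genome, window=500, step=100, groups=groups)

    def test_truncated_windows_dropped_and_counted(self):
        genome = GenomeModel({"chr1": 2_000},
                             [GeneRecord("edge", "chr1", "+", 100, 900, 800),
                              GeneRecord("mid", "chr1", "+", 1_000, 1_500, 500)])
        t = make_track({"chr1": [1.0] * 20})
        pm, _ = tss_profile(t, genome, window=500, step=100)
        assert pm.n_dropped == 1 and pm.gene_ids == ["mid"]


class TestRatioProfile:
    def _curve(self, vals):
        return pd.Series(vals, index=np.arange(-len(vals) / 2 + 0.5,
                                               len(vals) / 2, 1.0))

    def test_equal_curves_near_one(self):
        me2 = self._curve([2.0, 2.0, 2.0, 2.0])
        out = ratio_profile(me2, me2.copy(), epsilon=0.0)
        np.testing.assert_allclose(out.values, 1.0)

    def test_epsilon_guards_zero_denominator(self):
        me2 = self._curve([1.0, 1.0])
        me3 = self._curve([0.0, 0.0])
        out = ratio_profile(me2, me3, epsilon=0.01)
        assert np.all(np.isfinite(out.values))

    def test_halved_me2_doubled_me3_quarters_ratio(self):
        me2 = self._curve([4.0, 8.0, 2.0, 4.0])
        me3 = self._curve([2.0, 4.0, 1.0, 2.0])
        ctrl = ratio_profile(me2, me3, epsilon=0.0)
        mut = ratio_profile(me2 / 2, me3 * 2, epsilon=0.0)
        np.testing.assert_allclose(mut.values, ctrl.values / 4)

    def test_mismatched_offsets_rejected(self):
        a = pd.Series([1.0, 2.0], index=[-0.5, 0.5])
        b = pd.Series([1.0, 2.0], index=[-1.5, 1.5])
        with pytest.raises(ValueError, match="offsets"):
            ratio_profile(a, b)
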