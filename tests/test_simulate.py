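"""Synthetic-data generator: proteomes, ground truth, mixtures, peak tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from icatq.quantify import match_pairs, protein_rollup
from icatq.simulate import (
    GroundTruthProtein,
    MixtureDesign,
    MixtureModelParams,
    NoiseModel,
    TruthClass,
    assign_ground_truth,
    filament_abundance,
    generate_calibration_mixture,
    generate_peak_tables,
    simulate_proteome,
)


class TestSimulateProteome:
    def test_deterministic_for_fixed_seed(self):
        a = simulate_proteome(20, (50, 100), seed=9)
        b = simulate_proteome(20, (50, 100), seed=9)
        assert [(r.locus_tag, r.sequence) for r in a] == [
            (r.locus_tag, r.sequence) for r in b
        ]

    def test_zero_cys_prob(self):
        proteome = simulate_proteome(10, (50, 80), cys_prob=0.0, seed=1)
        assert all(r.n_cys == 0 for r in proteome)

    def test_cys_fraction_near_target(self):
        # mean Cys residue fraction within 3 SE of 0.9%
        p, n, length = 0.009, 5000, 300
        proteome = simulate_proteome(n, (length, length), cys_prob=p, seed=2)
        total = n * length
        frac = sum(r.n_cys for r in proteome) / total
        se = np.sqrt(p * (1 - p) / total)
        assert abs(frac - p) < 3 * se

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            simulate_proteome(0, (50, 80))
        with pytest.raises(ValueError):
            simulate_proteome(5, (80, 50))
        with pytest.raises(ValueError):
            simulate_proteome(5, (50, 80), cys_prob=1.5)


class TestAssignGroundTruth:
    def test_all_equal(self, sim_proteome):
        gt = assign_ground_truth(sim_proteome, {TruthClass.EQUAL: 1.0}, seed=1)
        assert all(t.abundance_het == t.abundance_veg for t in gt)

    def test_all_het_exclusive(self, sim_proteome):
        gt = assign_ground_truth(sim_proteome, {TruthClass.HET_EXCLUSIVE: 1.0}, seed=1)
        assert all(t.abundance_veg == 0 for t in gt)

    def test_degenerate_fold_range(self, sim_proteome):
        gt = assign_ground_truth(
            sim_proteome, {TruthClass.HET_ENRICHED: 1.0}, fold_range=(2.0, 2.0), seed=1
        )
        assert all(t.abundance_het / t.abundance_veg == pytest.approx(2.0) for t in gt)

    def test_fractions_must_sum_to_one(self, sim_proteome):
        with pytest.raises(ValueError, match="sum to 1"):
            assign_ground_truth(sim_proteome, {TruthClass.EQUAL: 0.7}, seed=1)

    def test_invariants_enforced_by_type(self):
        with pytest.raises(ValueError):
            GroundTruthProtein("P", 1.0, 0.5, TruthClass.HET_EXCLUSIVE)
        with pytest.raises(ValueError):
            GroundTruthProtein("P", 1.0, 0.5, TruthClass.EQUAL)


class TestFilamentAbundance:
    def test_het_exclusive_dilution(self):
        gt = GroundTruthProtein("P", 1.0, 0.0, TruthClass.HET_EXCLUSIVE)
        f = filament_abundance(gt, MixtureModelParams(0.075))
        assert f == pytest.approx(0.075)
        assert 1.0 / f == pytest.approx(13.33, abs=0.01)

    def test_equal_parts(self):
        gt = GroundTruthProtein("P", 3.0, 3.0, TruthClass.EQUAL)
        assert filament_abundance(gt, MixtureModelParams(0.075)) == pytest.approx(3.0)

    def test_veg_only(self):
        gt = GroundTruthProtein("P", 0.0, 1.0, TruthClass.VEG_EXCLUSIVE)
        assert filament_abundance(gt, MixtureModelParams(0.075)) == pytest.approx(0.925)


class TestGeneratePeakTables:
    def test_deterministic_for_fixed_seed(self, sim_proteome, sim_truth, params):
        noise = NoiseModel(0.11, 0.0, seed=3)
        a = generate_peak_tables(sim_truth, sim_proteome, params, noise)
        b = generate_peak_tables(sim_truth, sim_proteome, params, noise)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_equal_protein(self, sim_proteome, params, noiseless):
        gt = [GroundTruthProtein(sim_proteome[0].locus_tag, 5.0, 5.0, TruthClass.EQUAL)]
        peaks = generate_peak_tables(gt, sim_proteome, params, noiseless)
        if not peaks.empty:
            wide = peaks.pivot_table(
                index=["peptide", "replicate"], columns="channel", values="area"
            )
            assert np.allclose(wide["light"], wide["heavy"])

    def test_cys_free_protein_contributes_no_rows(self, params, noiseless):
        proteome = simulate_proteome(5, (60, 80), cys_prob=0.0, seed=4)
        gt = assign_ground_truth(proteome, {TruthClass.EQUAL: 1.0}, seed=4)
        peaks = generate_peak_tables(gt, proteome, params, noiseless)
        assert peaks.empty

    def test_het_exclusive_noise_free_hits_ceiling(self, sim_proteome, params, noiseless):
        cys_bearing = [r for r in sim_proteome if r.n_cys > 0][:5]
        gt = [
            GroundTruthProtein(r.locus_tag, 2.0, 0.0, TruthClass.HET_EXCLUSIVE)
            for r in cys_bearing
        ]
        peaks = generate_peak_tables(gt, sim_proteome, params, noiseless)
        wide = peaks.pivot_table(
            index=["locus_tag", "peptide", "replicate"], columns="channel", values="area"
        )
        ratios = wide["light"] / wide["heavy"]
        assert np.allclose(ratios, 1.0 / 0.075)

    def test_noise_free_recovery_equals_mixture_model(
        self, sim_proteome, sim_truth, params, noiseless
    ):
        # end-to-end: recovered fold ratio equals H/(f*H+(1-f)*V) to 1e-9
        peaks = generate_peak_tables(sim_truth, sim_proteome, params, noiseless)
        ratios, _ = protein_rollup(match_pairs(peaks), min_replicates=2)
        truth = {t.locus_tag: t for t in sim_truth}
        assert len(ratios) > 20
        for r in ratios:
            t = truth[r.locus_tag]
            expected = t.abundance_het / filament_abundance(t, params)
            assert 2.0 ** r.log2_ratio == pytest.approx(expected, abs=1e-9)


class TestCalibrationMixture:
    @pytest.mark.parametrize("expected", [1.0, 5.0, 0.2])
    def test_noise_free_exact_ratio(self, sim_proteome, sim_truth, params, expected, noiseless):
        design = MixtureDesign("d", expected)
        peaks = generate_calibration_mixture(design, sim_truth, sim_proteome, params, noiseless)
        wide = peaks.pivot_table(
            index=["locus_tag", "peptide", "replicate"], columns="channel", values="area"
        )
        assert np.allclose(wide["light"] / wide["heavy"], expected)

    def test_median_recovers_expected_ratio_under_noise(self, params):
        # Monte-Carlo: median protein ratio near 0.2 across seeds
        proteome = simulate_proteome(150, (60, 200), seed=21)
        gt = assign_ground_truth(proteome, {TruthClass.EQUAL: 1.0}, seed=22)
        design = MixtureDesign("1to5", 0.2)
        medians = []
        for seed in range(20):
            noise = NoiseModel(0.11, 0.0, seed=seed)
            peaks = generate_calibration_mixture(design, gt, proteome, params, noise)
            ratios, _ = protein_rollup(match_pairs(peaks), min_replicates=2)
            medians.append(np.median([2.0 ** r.log2_ratio for r in ratios]))
        assert np.mean(medians) == pytest.approx(0.2, rel=0.05)

    def test_censoring_inflates_spread_at_high_ratio(self, params):
        # detection limit censors the diluted channel more at 5:1 than at 1:1
        proteome = simulate_proteome(120, (60, 200), seed=31)
        gt = assign_ground_truth(proteome, {TruthClass.EQUAL: 1.0}, seed=32)
        spreads = {}
        for expected in (1.0, 5.0):
            noise = NoiseModel(0.35, detection_limit=3e4, seed=33)
            design = MixtureDesign("d", expected)
            peaks = generate_calibration_mixture(design, gt, proteome, params, noise)
            ratios, _ = protein_rollup(match_pairs(peaks), min_replicates=2)
            linear = np.array([2.0 ** r.log2_ratio for r in ratios]) / expected
            spreads[expected] = np.std(linear)
        assert spreads[5.0] > spreads[1.0]
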