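"""Generator determinism, noiseless exactness and parameter recovery."""

import numpy as np
import pytest

from commetab import ConfigurationError, preset
from commetab.community import biovolume_fraction, plate_counts_to_cfu
from commetab.electrochemistry import (peak_current_density, replicate_summary,
                                       to_current_density)
from commetab.metabolism import BIOMASS_E_PER_CMOL
from commetab.synthetic import (generate_current_trace, generate_expression,
                                generate_fluorescence, generate_image_stack,
                                generate_metabolite_series,
                                generate_plate_counts)


class TestCurrentTraceGenerator:
    def test_noiseless_trace_attains_peak(self, co_culture_noiseless):
        trace = generate_current_trace(co_culture_noiseless)
        j = to_current_density(trace).j_uA_per_cm2
        assert j.max() == pytest.approx(2.0)

    def test_zero_peak_gives_zero_trace(self):
        cfg = preset("co_culture", trace={"peak_j": 0.0, "noise_sd_j": 0.0})
        trace = generate_current_trace(cfg)
        assert np.all(trace.voltage_V == 0.0)

    def test_fixed_seed_is_deterministic(self):
        cfg = preset("co_culture", seed=1)
        a, b = generate_current_trace(cfg), generate_current_trace(cfg)
        np.testing.assert_array_equal(a.voltage_V, b.voltage_V)
        np.testing.assert_array_equal(a.time_s, b.time_s)

    def test_replicates_differ_but_share_ground_truth(self):
        cfg = preset("co_culture", seed=1)
        a = generate_current_trace(cfg, replicate=0)
        b = generate_current_trace(cfg, replicate=1)
        assert not np.array_equal(a.voltage_V, b.voltage_V)

    def test_noisy_replicates_recover_peak(self):
        # Monte-Carlo: peak estimator on 3 noisy replicates stays near truth
        cfg = preset("co_culture", seed=5)
        peaks = [peak_current_density(
            to_current_density(generate_current_trace(cfg, replicate=r)))[0]
            for r in range(3)]
        mean, _ = replicate_summary(peaks)
        assert mean == pytest.approx(2.0, abs=0.1)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            preset("co_culture", trace={"electrode_area_cm2": -1.0})
        with pytest.raises(ConfigurationError):
            preset("co_culture", trace={"resistor_ohm": 0.0})


class TestMetaboliteGenerator:
    def test_noiseless_formate_peak_at_48h(self, co_culture_noiseless):
        series = generate_metabolite_series(co_culture_noiseless)
        formate = series.conc_mM["formate"].to_numpy()
        i = int(np.argmax(formate))
        assert formate[i] == pytest.approx(45.0)
        assert series.time_h[i] == pytest.approx(48.0)

    def test_stoichiometric_mode_caps_formate(self):
        cfg = preset("co_culture", metabolite={"stoichiometric_mode": True,
                                               "glucose0_mM": 20.0})
        series = generate_metabolite_series(cfg)
        assert series.conc_mM["formate"].max() <= 40.0 + 1e-12

    def test_stoichiometric_mol_caps_hold_at_every_time(self):
        cfg = preset("co_culture", metabolite={"stoichiometric_mode": True})
        series = generate_metabolite_series(cfg)
        glucose = series.conc_mM["glucose"].to_numpy()
        consumed = glucose[0] - glucose
        cum_formate = np.maximum.accumulate(series.conc_mM["formate"].to_numpy())
        acetate = series.conc_mM["acetate"].to_numpy()
        assert np.all(cum_formate <= 2 * consumed + 1e-9)
        assert np.all(acetate <= 2 * consumed + 1e-9)

    def test_stoichiometric_carbon_closure(self):
        # glucose carbon consumed covers product carbon at every time
        cfg = preset("co_culture", metabolite={"stoichiometric_mode": True})
        series = generate_metabolite_series(cfg)
        glucose = series.conc_mM["glucose"].to_numpy()
        consumed_c = 6 * (glucose[0] - glucose)
        cum_formate = np.maximum.accumulate(series.conc_mM["formate"].to_numpy())
        product_c = cum_formate + 2 * series.conc_mM["acetate"].to_numpy()
        ratio = product_c[consumed_c > 0] / consumed_c[consumed_c > 0]
        assert np.all(ratio <= 1 + 1e-6)

    def test_glucose_monotone_non_increasing(self, co_culture_noiseless):
        series = generate_metabolite_series(co_culture_noiseless)
        assert np.all(np.diff(series.conc_mM["glucose"]) <= 1e-12)

    def test_all_zero_levels_give_flat_series(self):
        cfg = preset("co_culture", metabolite={
            "glucose0_mM": 0.0, "formate_peak_mM": 0.0, "acetate_level_mM": 0.0,
            "lactate_level_mM": 0.0, "noise_sd_mM": 0.0})
        series = generate_metabolite_series(cfg)
        assert (series.conc_mM.to_numpy() == 0.0).all()

    def test_bad_formate_timing_rejected(self):
        with pytest.raises(ConfigurationError):
            preset("co_culture", metabolite={"formate_peak_time_h": 100.0,
                                             "formate_depletion_time_h": 48.0})


class TestPlateCountGenerator:
    def test_binomial_split_recovers_fraction(self):
        # averaged over many plates the fluorescent share matches the truth
        cfg = preset("co_culture", seed=7, community={
            "total_cfu_per_ml": 1e10, "dilutions": (1e-6,), "n_replicates": 60})
        plates = generate_plate_counts(cfg, times_h=(24.0,),
                                       compartments=("planktonic",))
        total = sum(p.total_colonies for p in plates)
        fluor = sum(p.fluorescent_colonies for p in plates)
        assert 1 - fluor / total == pytest.approx(0.98, abs=0.01)

    def test_fraction_one_gives_no_fluorescent_colonies(self):
        cfg = preset("co_culture", seed=1,
                     community={"planktonic_ecoli_fraction": 1.0})
        plates = generate_plate_counts(cfg, compartments=("planktonic",))
        assert all(p.fluorescent_colonies == 0 for p in plates)

    def test_zero_cfu_gives_zero_counts(self):
        cfg = preset("co_culture", community={"total_cfu_per_ml": 0.0})
        plates = generate_plate_counts(cfg)
        assert all(p.total_colonies == 0 for p in plates)

    def test_negative_cfu_rejected(self):
        with pytest.raises(ConfigurationError):
            preset("co_culture", community={"total_cfu_per_ml": -1.0})


class TestImageStackGenerator:
    def test_noiseless_fraction_exact_up_to_voxel_quantisation(
            self, co_culture_noiseless):
        stack = generate_image_stack(co_culture_noiseless)
        n_dapi = stack.truth_dapi_mask.sum()
        ratio = stack.truth_gfp_mask.sum() / n_dapi
        assert ratio == pytest.approx(0.60, abs=1.0 / n_dapi)
        # noiseless channels segment exactly at a fixed threshold
        result = biovolume_fraction(stack, method="fixed", fixed_threshold=50.0)
        assert result.fraction == pytest.approx(ratio)

    def test_zero_fraction_gives_empty_gfp(self):
        cfg = preset("co_culture", community={
            "biofilm_so_biovolume_fraction": 0.0, "image_noise_sd": 0.0})
        stack = generate_image_stack(cfg)
        assert stack.gfp_voxels.sum() == 0.0

    def test_noisy_stacks_recover_fraction(self):
        # threshold-then-count vs the generator's ground-truth labels
        cfg = preset("co_culture", seed=3)
        fracs, truths = [], []
        for s in range(5):
            stack = generate_image_stack(cfg, seed_offset=s)
            fracs.append(biovolume_fraction(stack).fraction)
            truths.append(stack.truth_gfp_mask.sum() / stack.truth_dapi_mask.sum())
        assert np.mean(fracs) == pytest.approx(np.mean(truths), abs=0.03)


class TestFluorescenceGenerator:
    def test_zero_concentration_reads_background(self):
        cfg = preset("co_culture", flavin={
            "true_conc_nM": {"empty": 0.0}, "noise_sd_rfu": 0.0,
            "curve_intercept_rfu": 7.0, "blank_rfu": 50.0})
        df = generate_fluorescence(cfg)
        assert df.reading_rfu.tolist() == pytest.approx([57.0] * len(df))

    def test_linear_model_arithmetic(self):
        cfg = preset("co_culture", flavin={
            "true_conc_nM": {"x": 8.0}, "curve_slope_rfu_per_nM": 10.0,
            "curve_intercept_rfu": 0.0, "blank_rfu": 50.0, "noise_sd_rfu": 0.0})
        df = generate_fluorescence(cfg)
        wells = df[~df.is_blank].reading_rfu.tolist()
        assert wells == pytest.approx([130.0] * len(wells))

    def test_blank_wells_emitted(self, co_culture_noiseless):
        df = generate_fluorescence(co_culture_noiseless)
        assert df.is_blank.sum() == co_culture_noiseless.flavin.n_wells


class TestExpressionGenerator:
    def test_low_dispersion_ratio_approaches_fold_change(self):
        n = 200
        lfc = np.full(n, 1.0)
        cfg = preset("co_culture", seed=2, expression={
            "n_genes": n, "log2fc": lfc, "dispersion": 1e-4,
            "libsize_sd": 0.0, "n_replicates": 4})
        table = generate_expression(cfg)
        treated = table.counts[table.replicates("treated")].mean(axis=1)
        control = table.counts[table.replicates("control")].mean(axis=1)
        assert (treated / control).mean() == pytest.approx(2.0, rel=0.05)

    def test_fixed_seed_identical_tables(self):
        cfg = preset("co_culture", seed=9, expression={"n_genes": 50})
        a, b = generate_expression(cfg), generate_expression(cfg)
        assert a.counts.equals(b.counts) and a.length_bp.equals(b.length_bp)

    def test_replicate_minimum_enforced(self):
        with pytest.raises(ConfigurationError):
            preset("co_culture", expression={"n_replicates": 1})


def test_biomass_degree_of_reduction_constant():
    # CH1.8O0.5N0.2 carries 4.2 electron equivalents per C-mol
    assert BIOMASS_E_PER_CMOL == pytest.approx(4.2)
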