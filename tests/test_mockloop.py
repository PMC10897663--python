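"""Synthetic mock-loop generator: wave speed, simulation, point sets, cohorts."""

import math

import numpy as np
import pytest
from dataclasses import replace

from archpwv import (AortaSample, MockLoopConfig, TuningError,
                     estimate_transit_time, generate_cohort,
                     generate_point_set, moens_korteweg, pressure_summary,
                     simulate_sample)
from archpwv.centerline import length_from_point_sets
from archpwv.mockloop import CohortPopulation, modulus_for_wave_speed

from conftest import table1_sample


class TestMoensKorteweg:
    def test_identity_case(self):
        # E*h = 2*rho*r in consistent units -> c = 1
        assert moens_korteweg(2000.0, 1.0, 1.0, 1000.0) == pytest.approx(1.0)

    def test_sqrt_scaling_in_modulus(self):
        c1 = moens_korteweg(100e3, 2e-3, 11.4e-3, 1000.0)
        c4 = moens_korteweg(400e3, 2e-3, 11.4e-3, 1000.0)
        assert c4 == pytest.approx(2.0 * c1, rel=1e-12)

    def test_inverse_sqrt_scaling_in_radius(self):
        c1 = moens_korteweg(100e3, 2e-3, 10e-3, 1000.0)
        c2 = moens_korteweg(100e3, 2e-3, 40e-3, 1000.0)
        assert c2 == pytest.approx(c1 / 2.0, rel=1e-12)

    def test_hand_evaluated_value(self):
        # sqrt(400e3 * 2e-3 / (2 * 1000 * 11.4e-3)) = sqrt(800/22.8)
        c = moens_korteweg(400e3, 2e-3, 11.4e-3, 1000.0)
        assert c == pytest.approx(math.sqrt(800.0 / 22.8), rel=1e-12)
        assert c == pytest.approx(5.92, abs=5e-3)

    @pytest.mark.parametrize("bad", [
        dict(modulus_pa=0.0), dict(thickness_m=-1e-3),
        dict(radius_m=0.0), dict(density_kg_m3=-1.0)])
    def test_non_positive_arguments_rejected(self, bad):
        kwargs = dict(modulus_pa=100e3, thickness_m=2e-3,
                      radius_m=10e-3, density_kg_m3=1000.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            moens_korteweg(**kwargs)

    def test_round_trip_with_back_solver(self):
        E = modulus_for_wave_speed(3.53, 2e-3, 11.4e-3, 1000.0)
        assert moens_korteweg(E, 2e-3, 11.4e-3, 1000.0) == pytest.approx(3.53)


class TestSimulateSample:
    def test_mean_flow_matches_cardiac_output(self, mean_sample, quiet_config):
        sim = simulate_sample(mean_sample, quiet_config)
        mean_flow = np.mean(sim.proximal_flow.values)
        assert abs(mean_flow - quiet_config.cardiac_output_lpm) \
            <= 0.02 * quiet_config.cardiac_output_lpm

    def test_baseline_pressures_inside_windows(self, mean_sample, quiet_config):
        sim = simulate_sample(mean_sample, quiet_config)
        ps = pressure_summary(sim.zone3_pressure)
        win = quiet_config.pressure_windows_mmhg
        assert win["dbp"][0] <= ps.dbp_mmhg <= win["dbp"][1]
        assert win["sbp"][0] <= ps.sbp_mmhg <= win["sbp"][1]
        assert win["pp"][0] <= ps.pp_mmhg <= win["pp"][1]
        assert win["map"][0] <= ps.map_mmhg <= win["map"][1]

    def test_noise_free_delay_recovered_within_one_sample(self, mean_sample,
                                                          quiet_config):
        sim = simulate_sample(mean_sample, quiet_config)
        tt = estimate_transit_time(sim.proximal_flow, sim.distal_flow)
        err = abs(tt.transit_time_s - sim.truth.transit_time_s)
        assert err <= 1.0 / quiet_config.sampling_rate_hz

    def test_moens_korteweg_consistency_without_stiffening(self, mean_sample):
        cfg = MockLoopConfig(noise_sd=0.0, arch_type="III",
                             arch_stiffening_exponent=0.0)
        sim = simulate_sample(mean_sample, cfg)
        c_mk = moens_korteweg(mean_sample.wall_modulus_pa,
                              mean_sample.wall_thickness_m,
                              mean_sample.d2_mm / 2 * 1e-3,
                              mean_sample.fluid_density_kg_m3)
        assert sim.truth.wave_speed_m_s == pytest.approx(c_mk, rel=1e-12)

    def test_stent_limit_transit_time(self, mean_sample):
        # kappa -> large: covered segment traversed instantly
        cfg = MockLoopConfig(noise_sd=0.0, stent=True, stent_speed_factor=1e9)
        sim = simulate_sample(mean_sample, cfg)
        expected = (sim.truth.length_at_map_cm / 100.0 - 0.112) \
            / sim.truth.wave_speed_m_s
        assert sim.truth.transit_time_s == pytest.approx(expected, rel=1e-6)

    def test_stent_shortens_transit_time(self, mean_sample, quiet_config):
        native = simulate_sample(mean_sample, quiet_config)
        stented = simulate_sample(mean_sample, replace(quiet_config, stent=True))
        assert stented.truth.transit_time_s < native.truth.transit_time_s
        assert stented.truth.wave_speed_m_s == native.truth.wave_speed_m_s

    def test_type_iii_raises_map_and_wave_speed(self, mean_sample, quiet_config):
        base = simulate_sample(mean_sample, quiet_config)
        iii = simulate_sample(mean_sample, replace(quiet_config, arch_type="III"))
        assert iii.truth.map_mmhg > base.truth.map_mmhg
        assert iii.truth.wave_speed_m_s > base.truth.wave_speed_m_s
        # directional calibration: roughly +8 mmHg MAP and +8-9% wave speed
        assert 5.0 < iii.truth.map_mmhg - base.truth.map_mmhg < 12.0
        ratio = iii.truth.wave_speed_m_s / base.truth.wave_speed_m_s
        assert 1.06 < ratio < 1.11

    def test_unreachable_window_raises_named_tuning_error(self, mean_sample):
        cfg = MockLoopConfig(noise_sd=0.0,
                             pressure_windows_mmhg={
                                 "dbp": (75.0, 85.0), "sbp": (115.0, 118.0),
                                 "pp": (40.0, 50.0), "map": (90.0, 100.0)})
        with pytest.raises(TuningError, match="SBP"):
            simulate_sample(mean_sample, cfg)


class TestConfigInvariants:
    @pytest.mark.parametrize("bad", [
        dict(n_cycles=10), dict(sampling_rate_hz=50.0),
        dict(stent_speed_factor=0.5), dict(arch_resistance_factor=0.9),
        dict(arch_type="II"), dict(noise_sd=-0.1),
        dict(pressure_windows_mmhg={"dbp": (85.0, 75.0), "sbp": (115.0, 125.0),
                                    "pp": (40.0, 50.0), "map": (90.0, 100.0)}),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            MockLoopConfig(**bad)

    def test_tapering_enforced(self):
        with pytest.raises(ValueError, match="taper"):
            AortaSample("X", 20.0, 22.8, 16.3, 14.6, 36.2)


class TestGeneratePointSet:
    def test_noise_free_length_matches_table_value(self):
        sample = table1_sample(length_cm=36.2)
        ps = generate_point_set(sample, 100.0, jitter_px=0.0)
        fit = length_from_point_sets([ps, generate_point_set(sample, 80.0),
                                      generate_point_set(sample, 120.0)])
        lengths = dict(zip(fit.pressures_mmhg, fit.lengths_cm))
        assert lengths[100.0] == pytest.approx(36.2, abs=0.01)

    def test_zero_slope_gives_identical_lengths(self):
        sample = table1_sample(slope=0.0)
        fit = length_from_point_sets(
            [generate_point_set(sample, p) for p in (80.0, 100.0, 120.0)])
        assert np.ptp(fit.lengths_cm) < 1e-9

    def test_scale_invariance_in_px_per_cm(self, mean_sample):
        fit1 = length_from_point_sets(
            [generate_point_set(mean_sample, p, px_per_cm=40.0)
             for p in (80.0, 100.0, 120.0)])
        fit2 = length_from_point_sets(
            [generate_point_set(mean_sample, p, px_per_cm=80.0)
             for p in (80.0, 100.0, 120.0)])
        assert fit1.lengths_cm == pytest.approx(fit2.lengths_cm, rel=1e-12)

    def test_jitter_error_within_stated_bound(self, mean_sample):
        jitter, px_per_cm, n_points = 2.0, 40.0, 20
        truth = mean_sample.length_at_cm(100.0)
        bound = 2.0 * jitter * (n_points - 1) / px_per_cm
        for seed in range(10):
            ps = generate_point_set(mean_sample, 100.0, px_per_cm=px_per_cm,
                                    jitter_px=jitter, seed=seed,
                                    n_points=n_points)
            from archpwv import arc_length, calibrate_scale
            measured = arc_length(ps, calibrate_scale(ps))
            assert abs(measured - truth) <= bound

    def test_fewer_than_15_points_rejected(self, mean_sample):
        with pytest.raises(ValueError, match="15"):
            generate_point_set(mean_sample, 100.0, n_points=10)


class TestGenerateCohort:
    def test_same_seed_identical_cohorts(self):
        a = generate_cohort(10, seed=3)
        b = generate_cohort(10, seed=3)
        assert a == b

    def test_different_seed_differs(self):
        assert generate_cohort(5, seed=1) != generate_cohort(5, seed=2)

    def test_zero_variance_returns_population_means(self):
        pop = CohortPopulation(d_sds_mm=(0.0,) * 4, length_sd_cm=0.0,
                               length_slope_sd=0.0, wave_speed_sd_m_s=0.0)
        (s,) = generate_cohort(1, pop, seed=0)
        assert (s.d1_mm, s.d2_mm, s.d3_mm, s.d4_mm) == pop.d_means_mm
        assert s.length_ref_cm == pop.length_mean_cm

    def test_sample_means_converge_to_population(self):
        cohort = generate_cohort(300, seed=0)
        d2 = np.array([s.d2_mm for s in cohort])
        lengths = np.array([s.length_ref_cm for s in cohort])
        assert abs(d2.mean() - 22.8) < 0.4
        assert abs(lengths.mean() - 36.2) < 0.6

    def test_non_positive_n_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0)
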