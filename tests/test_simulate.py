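"""Synthetic experiment generator: kinetics, emission model, calibration,
environment and determinism."""

import numpy as np
import pandas as pd
import pytest

from soynose.acquisition import AcquisitionConfig, compute_sensitivity, estimate_baseline, peak_sensitivity
from soynose.chamber import baseline_qc
from soynose.radar import build_feature_table
from soynose.simulate import (
    DEFAULT_TARGET_PEAKS,
    EmissionParams,
    ExperimentConfig,
    SensorParams,
    calibrate_emission,
    default_emission_params,
    default_sensor_bank,
    emission_model,
    expected_peak_moments,
    expected_peak_pct,
    sensor_response,
    simulate_baseline_env,
    simulate_experiment,
)


class TestSensorResponse:
    def test_null_stimulus_flat_trace(self):
        p = SensorParams(r0_ohm=1000.0)
        tr = sensor_response(0.0, p, rng=None)
        assert np.allclose(tr.resistance_ohm, 1000.0)
        curve = compute_sensitivity(tr, estimate_baseline(tr))
        assert peak_sensitivity(curve) == 0.0

    def test_steady_state_drop(self):
        # for t >> tau the sensitivity approaches -100*d, d = g*c/(1+g*c)
        p = SensorParams(r0_ohm=1000.0, gain=1.0, tau_rise_s=5.0)
        c = 0.5
        d = c / (1 + c)
        tr = sensor_response(c, p, rng=None)
        s_end = 100.0 * (tr.resistance_ohm[-1] - 1000.0) / 1000.0
        assert s_end == pytest.approx(-100.0 * d, abs=1e-6)

    def test_first_order_value_at_tau(self):
        p = SensorParams(r0_ohm=1000.0, gain=1.0, tau_rise_s=25.0, delay_s=0.0)
        c = 1.0
        d = 0.5
        tr = sensor_response(c, p, rng=None)
        idx = int(np.argmin(np.abs(tr.times_s - p.tau_rise_s)))
        s_at_tau = 100.0 * (tr.resistance_ohm[idx] - 1000.0) / 1000.0
        assert s_at_tau == pytest.approx(-100.0 * d * (1.0 - np.exp(-1.0)), rel=1e-9)

    def test_delay_holds_baseline(self):
        p = SensorParams(r0_ohm=1000.0, gain=1.0, delay_s=10.0)
        tr = sensor_response(2.0, p, rng=None)
        assert np.allclose(tr.resistance_ohm[:10], 1000.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            sensor_response(-1.0, SensorParams(r0_ohm=100.0))


class TestEmissionModel:
    def null_params(self):
        return EmissionParams(base_concentration=1.0, stress_effect=1.0, afternoon_effect=1.0)

    def test_null_configuration_label_independent(self):
        p = self.null_params()
        a = emission_model(15, "morning", "irrigated", 1.0, p)
        b = emission_model(25, "morning", "non_irrigated", 1.0, p)
        c = emission_model(15, "afternoon", "irrigated", 1.0, p)
        assert np.allclose(a, b) and np.allclose(a, c)

    def test_multiplicative_structure(self):
        p = EmissionParams(base_concentration=2.0, stress_effect=1.5,
                           afternoon_effect=1.2, growth_slope=0.1)
        c = emission_model(13, "afternoon", "non_irrigated", 0.9, p, das0=11)
        expected = 2.0 * np.exp(0.1 * 2) * 1.2 * 1.5 * 0.9
        assert np.allclose(c, expected)

    def test_scaled_stress_null_and_square(self):
        p = default_emission_params()
        null = p.scaled_stress(0.0)
        assert np.allclose(null.stress_effect, 1.0)
        strong = p.scaled_stress(2.0)
        assert np.allclose(strong.stress_effect, p.stress_effect**2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            EmissionParams(base_concentration=-1.0)
        with pytest.raises(ValueError):
            emission_model(15, "midnight", "irrigated", 1.0, self.null_params())


class TestCalibration:
    def test_sigma_zero_closed_form(self):
        sp = SensorParams(r0_ohm=1e6, delay_s=10.0)
        cfg = AcquisitionConfig()
        x = 0.4
        frac = 1.0 - np.exp(-(239.0 - 10.0) / sp.tau_rise_s)
        assert expected_peak_pct(x, sp, cfg, 0.0) == pytest.approx(
            -100.0 * frac * x / (1 + x), rel=1e-12
        )

    def test_solved_parameters_reproduce_targets(self):
        em = default_emission_params()
        bank = default_sensor_bank()
        cfg = AcquisitionConfig()
        sigma = float(np.hypot(em.weather_noise_sd, em.channel_noise_sd))
        for i, sp in enumerate(bank):
            for phase, mult in (("irrigated", 1.0), ("non_irrigated", em.stress_effect[i])):
                x = em.base_concentration[i] * sp.gain * mult
                mean = 0.5 * (
                    expected_peak_pct(x, sp, cfg, sigma)
                    + expected_peak_pct(x * em.afternoon_effect, sp, cfg, sigma)
                )
                assert mean == pytest.approx(DEFAULT_TARGET_PEAKS[phase][i], abs=1e-8)

    def test_stress_raises_concentration(self):
        em = default_emission_params()
        assert np.all(em.stress_effect > 1.0)

    def test_moments_match_quadrature_mean(self):
        em = default_emission_params()
        sp = default_sensor_bank()[1]
        cfg = AcquisitionConfig()
        x = em.base_concentration[1]
        mean, sd = expected_peak_moments(
            x, sp, cfg,
            weather_sd=em.weather_noise_sd, channel_sd=em.channel_noise_sd,
            afternoon_effect=em.afternoon_effect,
        )
        assert mean == pytest.approx(DEFAULT_TARGET_PEAKS["irrigated"][1], abs=1e-6)
        assert 2.0 < sd < 6.0  # same order as the reported session scatter

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_emission(targets={
                "irrigated": (5.0,) * 6, "non_irrigated": (-20.0,) * 6,
            })


class TestSimulateExperiment:
    def test_session_and_trace_counts(self, small_experiment):
        cfg = small_experiment.config
        n_days = cfg.das_end - cfg.das_start + 1
        assert len(small_experiment.sessions) == cfg.n_plants * n_days * 2
        for s in small_experiment.sessions[:5]:
            assert set(s.traces) == set(range(1, 7))
            assert all(len(reps) == cfg.replicates for reps in s.traces.values())
            assert all(len(tr) == 240 for reps in s.traces.values() for tr in reps)

    def test_determinism_same_seed(self):
        cfg = dict(n_plants=1, seed=11)
        a = simulate_experiment(ExperimentConfig(**cfg))
        b = simulate_experiment(ExperimentConfig(**cfg))
        pd.testing.assert_frame_equal(a.env, b.env)
        pd.testing.assert_frame_equal(a.acquisitions_frame(), b.acquisitions_frame())

    def test_different_seed_differs(self):
        a = simulate_experiment(ExperimentConfig(n_plants=1, seed=1))
        b = simulate_experiment(ExperimentConfig(n_plants=1, seed=2))
        assert not np.allclose(
            a.sessions[0].traces[1][0].resistance_ohm,
            b.sessions[0].traces[1][0].resistance_ohm,
        )

    def test_subset_reproducibility(self):
        """Per-session streams are keyed by (plant, das, period), so a
        1-plant run reproduces plant 1 of a 2-plant run exactly."""
        a = simulate_experiment(ExperimentConfig(n_plants=2, seed=5))
        b = simulate_experiment(ExperimentConfig(n_plants=1, seed=5))
        sa = next(s for s in a.sessions if s.plant == 1 and s.das == 15 and s.period == "morning")
        sb = next(s for s in b.sessions if s.plant == 1 and s.das == 15 and s.period == "morning")
        assert np.allclose(sa.traces[3][2].resistance_ohm, sb.traces[3][2].resistance_ohm)

    def test_env_physical_bounds(self, small_experiment):
        env = small_experiment.env
        assert env["rh_int_pct"].between(0, 100).all()
        assert env["rh_ext_pct"].between(0, 100).all()
        assert (env["co2_int_ppm"] >= 0).all() and (env["lux_ext"] >= 0).all()
        # 12 five-minute samples per session window
        n_days = small_experiment.config.das_end - small_experiment.config.das_start + 1
        assert len(env) == small_experiment.config.n_plants * n_days * 2 * 12

    def test_afternoon_radar_area_larger(self, small_experiment):
        table, _ = build_feature_table(small_experiment.sessions)
        am = table[table.period == "morning"]["radar_area"].mean()
        pm = table[table.period == "afternoon"]["radar_area"].mean()
        assert pm > am

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(das_start=5)
        with pytest.raises(ValueError):
            ExperimentConfig(n_plants=0)


class TestBaselineEnvironment:
    def test_empty_chamber_ranges_within_bands(self):
        env = simulate_baseline_env(seed=3, days=3)
        qc = baseline_qc(env[["temp_int_c", "rh_int_pct", "co2_int_ppm"]])
        assert qc["temp_int_c"].range <= 4.0
        assert qc["rh_int_pct"].range <= 9.0
        assert qc["co2_int_ppm"].range <= 20.0
        assert qc["temp_int_c"].min >= 23.0 and qc["temp_int_c"].max <= 27.0
        assert qc["rh_int_pct"].min >= 16.0 and qc["rh_int_pct"].max <= 25.0
        assert qc["co2_int_ppm"].min >= 250.0 and qc["co2_int_ppm"].max <= 270.0

    def test_cadence_and_length(self):
        env = simulate_baseline_env(seed=0, days=2)
        assert len(env) == 2 * 24 * 12
        ts = pd.to_datetime(env["timestamp"])
        assert (ts.diff().dropna() == pd.Timedelta(minutes=5)).all()
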