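"""Synthetic cohort generator: pools, sEMG, strain, sessions, cohorts."""

import numpy as np
import pytest
from dataclasses import replace

from sarcoscreen.cohort import (
    SimulationConfig,
    build_motor_unit_pool,
    generate_cohort,
    generate_session,
    load_cohort,
    muap_kernel,
    simulate_semg,
    simulate_strain,
    trapezoid_effort,
    write_cohort,
)
from sarcoscreen.preprocess import median_frequency
from sarcoscreen.screening import classify_awgs


class TestMotorUnitPool:
    def test_pool_size_and_threshold_ordering(self, default_config):
        pool = build_motor_unit_pool("healthy", default_config, np.random.default_rng(1))
        assert len(pool) == default_config.n_motor_units_healthy
        thresholds = [mu.recruitment_threshold for mu in pool]
        assert all(a < b for a, b in zip(thresholds, thresholds[1:]))

    def test_size_principle_amplitude_monotone(self, default_config):
        pool = build_motor_unit_pool("healthy", default_config, np.random.default_rng(1))
        amps = [mu.muap_amplitude for mu in pool]
        assert all(a < b for a, b in zip(amps, amps[1:]))

    def test_sarcopenic_durations_scale_matched(self):
        # equal pool sizes so the random draws pair up unit-for-unit
        config = SimulationConfig(n_motor_units_sarcopenic=60)
        healthy = build_motor_unit_pool("healthy", config, np.random.default_rng(7))
        sarc = build_motor_unit_pool("sarcopenia", config, np.random.default_rng(7))
        for h, s in zip(healthy, sarc):
            assert s.muap_duration == pytest.approx(
                config.duration_scale_sarcopenic * h.muap_duration
            )

    def test_single_unit_pool(self):
        config = SimulationConfig(n_motor_units_healthy=1)
        pool = build_motor_unit_pool("healthy", config, np.random.default_rng(7))
        assert len(pool) == 1 and pool[0].recruitment_threshold < 1

    def test_nonpositive_count_is_configuration_error(self):
        config = SimulationConfig(n_motor_units_healthy=0)
        with pytest.raises(ValueError):
            build_motor_unit_pool("healthy", config, np.random.default_rng(0))


class TestSimulateSEMG:
    def test_zero_effort_zero_noise_is_silent(self, default_config):
        config = replace(default_config, noise_sd=0.0)
        pool = build_motor_unit_pool("healthy", config, np.random.default_rng(2))
        out = simulate_semg(pool, np.zeros(2000), config, np.random.default_rng(2))
        assert np.all(out == 0)

    def test_effort_outside_unit_interval_raises(self, default_config):
        pool = build_motor_unit_pool("healthy", default_config, np.random.default_rng(2))
        with pytest.raises(ValueError):
            simulate_semg(pool, np.full(100, 1.5), default_config, np.random.default_rng(0))

    def test_single_unit_matches_direct_convolution_of_spikes(self):
        """With one unit and no noise, the signal is exactly the MUAP kernel
        convolved with the logged impulse train."""
        config = SimulationConfig(n_motor_units_healthy=1, noise_sd=0.0)
        pool = build_motor_unit_pool("healthy", config, np.random.default_rng(3))
        effort = np.ones(4000)
        out, spikes = simulate_semg(
            pool, effort, config, np.random.default_rng(3), return_spikes=True
        )
        train = np.zeros(4000)
        idx = np.round(spikes[0] * config.sampling_rate).astype(int)
        np.add.at(train, idx[idx < 4000], 1.0)
        kernel = muap_kernel(
            pool[0].muap_duration, pool[0].muap_amplitude, config.sampling_rate
        )
        oracle = np.convolve(train, kernel, mode="same")
        assert np.allclose(out, oracle, atol=1e-12)

    def test_median_frequency_separation_between_groups(self, default_config):
        effort = np.ones(5000)
        mfs = {}
        for group in ("healthy", "sarcopenia"):
            vals = []
            for s in range(10):
                rng = np.random.default_rng(1000 + s)
                pool = build_motor_unit_pool(group, default_config, rng)
                sig = simulate_semg(pool, effort, default_config, rng)
                vals.append(median_frequency(sig, default_config.sampling_rate))
            mfs[group] = np.mean(vals)
        assert mfs["healthy"] - mfs["sarcopenia"] >= 15.0

    def test_rms_scales_linearly_with_unit_amplitude(self):
        config = SimulationConfig(noise_sd=0.0, n_motor_units_healthy=10)
        pool = build_motor_unit_pool("healthy", config, np.random.default_rng(5))
        doubled = [replace(mu, muap_amplitude=2 * mu.muap_amplitude) for mu in pool]
        effort = np.ones(3000)
        a = simulate_semg(pool, effort, config, np.random.default_rng(42))
        b = simulate_semg(doubled, effort, config, np.random.default_rng(42))
        assert np.sqrt(np.mean(b**2)) == pytest.approx(
            2 * np.sqrt(np.mean(a**2)), rel=1e-9
        )


class TestSimulateStrain:
    def _quiet(self, config):
        return replace(config, strain_noise_sd=0.0)

    def test_constant_effort_decays_to_zero(self, default_config, healthy_profile):
        config = self._quiet(default_config)
        out = simulate_strain(
            np.ones(3000), healthy_profile, config, np.random.default_rng(0)
        )
        assert abs(out[-1]) < 1e-3 * np.max(np.abs(out))

    def test_ramp_plateau_matches_first_order_closed_form(
        self, default_config, healthy_profile
    ):
        config = self._quiet(default_config)
        fs, tau = config.sampling_rate, config.strain_tau_s
        ramp = np.linspace(0, 1, int(fs), endpoint=False)  # 1-s ramp
        out = simulate_strain(ramp, healthy_profile, config, np.random.default_rng(0))
        slope = healthy_profile.grip_strength / 1.0  # kg/s
        t = np.arange(ramp.size) / fs
        expected = config.strain_gain * tau * slope * (1 - np.exp(-t / tau))
        assert np.allclose(out[50:], expected[50:], rtol=0.02, atol=1e-4)

    def test_peak_output_linear_in_grip_strength(self, default_config, healthy_profile):
        config = self._quiet(default_config)
        strong = replace(healthy_profile, grip_strength=30.0)
        weak = replace(healthy_profile, grip_strength=15.0)
        effort = trapezoid_effort(config)
        a = simulate_strain(effort, strong, config, np.random.default_rng(0))
        b = simulate_strain(effort, weak, config, np.random.default_rng(0))
        assert np.max(np.abs(a)) == pytest.approx(2 * np.max(np.abs(b)), rel=1e-6)


class TestGenerateSession:
    def test_protocol_three_trials_of_5000_samples(
        self, default_config, healthy_profile
    ):
        rec = generate_session(healthy_profile, default_config, np.random.default_rng(0))
        assert len(rec.trial_boundaries) == 3
        for start, stop in rec.trial_boundaries:
            assert stop - start == 5000
        # rests between trials fall in the 4-6 s protocol range
        gaps = [
            (b2[0] - b1[1]) / default_config.sampling_rate
            for b1, b2 in zip(rec.trial_boundaries, rec.trial_boundaries[1:])
        ]
        assert all(4.0 <= g <= 6.0 for g in gaps)

    def test_bit_identical_under_fixed_seed(self, default_config, healthy_profile):
        a = generate_session(healthy_profile, default_config, np.random.default_rng(9))
        b = generate_session(healthy_profile, default_config, np.random.default_rng(9))
        for name in a.channels:
            assert np.array_equal(a.channels[name], b.channels[name])

    def test_sarcopenic_raw_envelope_is_attenuated(
        self, default_config, healthy_profile, sarcopenic_profile
    ):
        h_amp, s_amp = [], []
        for s in range(6):
            rec_h = generate_session(
                healthy_profile, default_config, np.random.default_rng(50 + s)
            )
            rec_s = generate_session(
                sarcopenic_profile, default_config, np.random.default_rng(50 + s)
            )
            for rec, acc in ((rec_h, h_amp), (rec_s, s_amp)):
                start, stop = rec.trial_boundaries[0]
                acc.append(np.sqrt(np.mean(rec.channels["br_semg"][start:stop] ** 2)))
        assert np.mean(s_amp) < np.mean(h_amp)


class TestGenerateCohort:
    def test_smallest_balanced_cohort(self):
        recordings, profiles = generate_cohort(n_subjects=2, prevalence=0.5, seed=1)
        assert sorted(p.group_label for p in profiles) == ["healthy", "sarcopenia"]
        assert len(recordings) == 2

    def test_labels_consistent_with_awgs_rule(self, small_cohort):
        _, profiles = small_cohort
        for p in profiles:
            res = classify_awgs(p.sex, p.grip_strength, p.smi, p.chair_stand_time)
            assert res.classification == p.group_label

    def test_deterministic_given_seed(self):
        a_recs, a_profs = generate_cohort(n_subjects=3, prevalence=0.5, seed=21)
        b_recs, b_profs = generate_cohort(n_subjects=3, prevalence=0.5, seed=21)
        assert a_profs == b_profs
        for ra, rb in zip(a_recs, b_recs):
            for name in ra.channels:
                assert np.array_equal(ra.channels[name], rb.channels[name])

    @pytest.mark.parametrize("bad", [{"n_subjects": 1}, {"prevalence": 0.0}, {"prevalence": 1.0}])
    def test_invalid_cohort_parameters_raise(self, bad):
        kwargs = {"n_subjects": 4, "prevalence": 0.5, "seed": 0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            generate_cohort(**kwargs)

    def test_csv_manifest_roundtrip(self, tmp_path):
        recordings, profiles = generate_cohort(n_subjects=2, prevalence=0.5, seed=5)
        manifest = write_cohort(recordings, profiles, tmp_path, seed=5)
        loaded_recs, loaded_profs = load_cohort(manifest)
        assert [p.subject_id for p in loaded_profs] == [p.subject_id for p in profiles]
        assert loaded_profs[0].group_label == profiles[0].group_label
        for ra, rb in zip(recordings, loaded_recs):
            assert ra.trial_boundaries == rb.trial_boundaries
            for name in ra.channels:
                assert np.allclose(ra.channels[name], rb.channels[name], atol=2e-6, rtol=1e-4)


def test_config_json_roundtrip(tmp_path, default_config):
    path = tmp_path / "config.json"
    default_config.to_json(path)
    assert SimulationConfig.from_json(path) == default_config
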