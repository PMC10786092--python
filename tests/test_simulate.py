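"""Generator contracts: determinism, embedded geometry, behavior bounds."""

import numpy as np
import pytest

import rsamediate as rm
from rsamediate.simulate import condition_signs, dimension_patterns


class TestParticipantEEG:
    def test_no_signal_no_noise_gives_identical_trials(self):
        cfg = rm.SimulationConfig(
            n_channels=6,
            trials_per_condition=3,
            dimension_amplitudes={"race": 0.0, "pain": 0.0, "gender": 0.0},
            noise_variance_uv2=0.0,
            seed=1,
        )
        ep = rm.simulate_participant_eeg(cfg, race_strength=1.0, seed=2)
        assert np.allclose(ep.data, ep.data[0])

    def test_determinism_bit_identical(self, small_config):
        a = rm.simulate_participant_eeg(small_config, 1.3, seed=9)
        b = rm.simulate_participant_eeg(small_config, 1.3, seed=9)
        assert np.array_equal(a.data, b.data)
        assert (a.condition_labels == b.condition_labels).all()

    def test_different_seed_differs(self, small_config):
        a = rm.simulate_participant_eeg(small_config, 1.0, seed=1)
        b = rm.simulate_participant_eeg(small_config, 1.0, seed=2)
        assert not np.array_equal(a.data, b.data)

    def test_negative_race_strength_rejected(self, small_config):
        with pytest.raises(rm.ConfigError, match="race_strength"):
            rm.simulate_participant_eeg(small_config, -0.5, seed=1)

    def test_invalid_config_names_field(self):
        with pytest.raises(rm.ConfigError, match="trials_per_condition"):
            rm.SimulationConfig(trials_per_condition=0)
        with pytest.raises(rm.ConfigError, match="epoch_window_ms"):
            rm.SimulationConfig(epoch_window_ms=(100.0, 600.0))
        with pytest.raises(rm.ConfigError, match="dimension_amplitudes"):
            rm.SimulationConfig(
                dimension_amplitudes={"race": -1.0, "pain": 1.0, "gender": 1.0}
            )

    def test_condition_mean_separation_matches_amplitude(self):
        """Noise-free between-category topography difference has norm
        amplitude * envelope, along the dimension's pattern."""
        cfg = rm.SimulationConfig(
            n_channels=10, trials_per_condition=1, noise_variance_uv2=0.0, seed=3
        )
        ep = rm.simulate_participant_eeg(cfg, race_strength=1.0, seed=0)
        means = np.zeros((8, 10))
        ti = ep.time_index(140.0)
        idx = ep.condition_index()
        for c in range(8):
            means[c] = ep.data[idx == c, :, ti].mean(axis=0)
        # race contrast at the race peak: first 4 conditions are Asian
        diff = means[:4].mean(axis=0) - means[4:].mean(axis=0)
        expected = cfg.dimension_amplitudes["race"]  # envelope = 1 at peak
        assert np.linalg.norm(diff) == pytest.approx(expected, rel=1e-10)
        v = dimension_patterns(cfg)[0]
        assert abs(abs(diff @ v) - np.linalg.norm(diff)) < 1e-10

    def test_race_beta_exceeds_pain_beta_at_peak(self, default_config):
        """Downstream race beta at 140 ms exceeds the pain beta for most
        seeds (race amplitude 2 vs pain 1); 10-seed spot check of the
        full-pipeline Monte-Carlo property."""
        wins = 0
        for seed in range(10):
            ep = rm.simulate_participant_eeg(default_config, 1.0, seed=seed)
            bt = rm.beta_timecourse(ep.crop(130, 150))
            i = list(bt.times_ms).index(140.0)
            wins += bt.betas[i, 0] > bt.betas[i, 1]
        assert wins >= 9

    def test_patterns_orthonormal(self, default_config):
        v = dimension_patterns(default_config)
        assert np.allclose(v @ v.T, np.eye(3), atol=1e-10)

    def test_condition_signs_code_half_contrasts(self):
        s = condition_signs()
        assert s.shape == (8, 3)
        assert set(np.unique(s)) == {-0.5, 0.5}
        # each dimension splits 4 vs 4
        assert np.allclose(s.sum(axis=0), 0)


class TestBehavior:
    def test_zero_paths_zero_noise_constant_difference(self):
        cfg = rm.SimulationConfig(
            mediation_paths={"b": 0.0, "c_prime_EG": 0.0, "c_prime_RI": 0.0},
            behavior_noise_sd=0.0,
            low_anchor_noise_sd=0.0,
            seed=4,
        )
        diffs = set()
        for seed in range(5):
            hi, lo = rm.simulate_behavior(
                {"EG": seed - 2.0, "RI": 1.0}, race_indicator=float(seed), config=cfg, seed=seed
            )
            diffs.add(round(hi - lo, 12))
        assert len(diffs) == 1
        (d,) = diffs
        assert d == pytest.approx(2.8 - 1.5)

    def test_intensities_within_shock_scale(self, default_config):
        rng = np.random.default_rng(0)
        for seed in range(200):
            hi, lo = rm.simulate_behavior(
                {"EG": rng.standard_normal(), "RI": rng.standard_normal()},
                race_indicator=float(3 * rng.standard_normal()),
                config=default_config,
                seed=seed,
            )
            assert 0.8 <= lo <= 3.4
            assert 0.8 <= hi <= 3.4

    def test_slope_recovery_on_large_cohort(self):
        cfg = rm.SimulationConfig(
            mediation_paths={"b": 0.3, "c_prime_EG": 0.0, "c_prime_RI": 0.0}, seed=6
        )
        rng = np.random.default_rng(1)
        race = rng.standard_normal(500)
        diffs = []
        for i, r in enumerate(race):
            hi, lo = rm.simulate_behavior(
                {"EG": 0.0, "RI": 0.0}, float(r), cfg, seed=i
            )
            diffs.append(hi - lo)
        slope = np.polyfit(race, diffs, 1)[0]
        assert slope == pytest.approx(0.3, abs=0.05)


class TestCohort:
    def test_single_participant(self, small_config):
        eps, table = rm.simulate_cohort(small_config, 1, seed=5)
        assert len(eps) == 1 and len(table) == 1

    def test_rejects_empty_cohort(self, small_config):
        with pytest.raises(rm.ConfigError, match="n_participants"):
            rm.simulate_cohort(small_config, 0, seed=5)

    def test_ground_truth_columns_and_bounds(self, small_config):
        eps, table = rm.simulate_cohort(small_config, 12, seed=5)
        for col in ("true_EG", "true_RI", "true_race_z", "true_race_multiplier"):
            assert col in table.columns
        assert (table["true_race_multiplier"] >= 0).all()
        assert table["punishment_high"].between(0.8, 3.4).all()
        items = [c for c in table.columns if c.startswith("item_")]
        assert len(items) == 9
        assert table[items].isin(range(1, 8)).all().all()

    def test_uncorrelated_traits_sample_correlation_small(self):
        cfg = rm.SimulationConfig(
            n_channels=4, trials_per_condition=1, trait_correlation=0.0, seed=8
        )
        _, table = rm.simulate_cohort(cfg, 1000, seed=2)
        r = np.corrcoef(table["true_EG"], table["true_RI"])[0, 1]
        assert abs(r) < 0.1

    def test_trait_modulates_race_strength_sign(self, small_config):
        """gamma_EG > 0 and gamma_RI < 0 must show up in the latent race
        strength of a large cohort (item-level recovery is covered by the
        acceptance suite on the full pipeline)."""
        _, table = rm.simulate_cohort(small_config, 400, seed=3)
        r_eg = np.corrcoef(table["true_EG"], table["true_race_z"])[0, 1]
        r_ri = np.corrcoef(table["true_RI"], table["true_race_z"])[0, 1]
        assert r_eg > 0.1
        assert r_ri < -0.1

    def test_determinism(self, small_config):
        eps1, t1 = rm.simulate_cohort(small_config, 3, seed=7)
        eps2, t2 = rm.simulate_cohort(small_config, 3, seed=7)
        assert np.array_equal(eps1[0].data, eps2[0].data)
        assert t1.equals(t2)


class TestConfigSerialization:
    def test_yaml_round_trip(self, default_config):
        text = default_config.to_yaml()
        again = rm.SimulationConfig.from_yaml(text)
        assert again == default_config

    def test_unknown_keys_rejected(self):
        with pytest.raises(rm.ConfigError, match="unknown"):
            rm.SimulationConfig.from_dict({"n_channels": 4, "bogus": 1})


class TestEpochIO:
    def test_save_load_round_trip(self, tmp_path, small_config):
        cfg = small_config.replace(trials_per_condition=2)
        ep = rm.simulate_participant_eeg(cfg, 1.0, seed=1)
        ep.save(tmp_path / "p000")
        back = rm.EpochedEEG.load(tmp_path / "p000")
        assert np.allclose(back.data, ep.data)
        assert (back.condition_labels == ep.condition_labels).all()
        assert np.allclose(back.times_ms, ep.times_ms)
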