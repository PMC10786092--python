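"""Model RDMs, shrinkage covariance and Mahalanobis geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from sklearn.covariance import LedoitWolf

import rsamediate as rm
from rsamediate.rdm import devectorize, pair_indices


class TestModelRDMs:
    def test_between_within_counts(self):
        models = rm.build_model_rdms()
        for dim in rm.DIMENSIONS:
            mat = models[dim]
            assert mat.sum() == 32  # 4x4 between pairs, both triangles
            assert np.allclose(mat, mat.T)
            assert np.all(np.diag(mat) == 0)
            i, j = pair_indices()
            assert mat[i, j].sum() == 16

    def test_relabeling_permutes_consistently(self, rng):
        perm = rng.permutation(8)
        order = [rm.CONDITIONS[k] for k in perm]
        base = rm.build_model_rdms()
        shuffled = rm.build_model_rdms(order)
        for dim in rm.DIMENSIONS:
            assert np.array_equal(shuffled[dim], base[dim][np.ix_(perm, perm)])

    def test_duplicate_conditions_rejected(self):
        order = [rm.CONDITIONS[0]] * 8
        with pytest.raises(rm.ConfigError):
            rm.build_model_rdms(order)


class TestConditionMeans:
    def test_matches_brute_force_mean(self, small_epochs):
        t = 140.0
        means = rm.condition_mean_topographies(small_epochs, t)
        ti = small_epochs.time_index(t)
        idx = small_epochs.condition_index()
        for c in range(8):
            expected = small_epochs.data[idx == c, :, ti].sum(axis=0) / (idx == c).sum()
            assert np.allclose(means[c], expected, atol=1e-12)

    def test_single_trial_condition_returns_that_trial(self):
        cfg = rm.SimulationConfig(n_channels=5, trials_per_condition=1, seed=2)
        ep = rm.simulate_participant_eeg(cfg, 1.0, seed=1)
        means = rm.condition_mean_topographies(ep, 0.0)
        ti = ep.time_index(0.0)
        idx = ep.condition_index()
        for c in range(8):
            assert np.allclose(means[c], ep.data[idx == c][0, :, ti])

    def test_missing_condition_raises(self, small_epochs):
        keep = np.array(
            [tuple(r) != rm.CONDITIONS[0] for r in small_epochs.condition_labels]
        )
        ep = small_epochs.select_trials(keep)
        with pytest.raises(rm.MissingConditionError):
            rm.condition_mean_topographies(ep, 0.0)


class TestShrinkageCovariance:
    def test_matches_sklearn_ledoit_wolf(self, rng):
        """Independent oracle: sklearn's analytic Ledoit-Wolf on centered data."""
        for _ in range(5):
            x = rng.standard_normal((40, 6)) @ rng.standard_normal((6, 6))
            xc = x - x.mean(axis=0)
            ours = rm.shrinkage_covariance(xc)
            ref = LedoitWolf(assume_centered=True).fit(xc)
            assert np.allclose(ours.matrix, ref.covariance_, atol=1e-10)
            assert ours.shrinkage_intensity == pytest.approx(ref.shrinkage_, abs=1e-12)

    def test_intensity_bounds_and_diagonal_population(self, rng):
        x = rng.standard_normal((500, 4)) * np.array([1.0, 2.0, 0.5, 1.5])
        est = rm.shrinkage_covariance(x - x.mean(axis=0))
        assert 0.0 <= est.shrinkage_intensity <= 1.0
        off = est.matrix[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_large_n_approaches_sample_covariance(self, rng):
        # anisotropic, correlated population: the identity target is a poor
        # fit, so the analytic intensity must vanish as n grows
        mix = np.array([[2.0, 0.7, 0.0], [0.0, 1.0, 0.4], [0.0, 0.0, 0.3]])
        x = rng.standard_normal((5000, 3)) @ mix
        xc = x - x.mean(axis=0)
        est = rm.shrinkage_covariance(xc)
        sample = xc.T @ xc / len(xc)
        assert est.shrinkage_intensity < 0.02
        assert np.allclose(est.matrix, sample, atol=0.02)

    def test_degenerate_inputs_flagged(self):
        with pytest.raises(rm.DegenerateDataError):
            rm.shrinkage_covariance(np.zeros((10, 4)))
        with pytest.raises(rm.DegenerateDataError):
            rm.shrinkage_covariance(np.ones((1, 4)))


class TestMahalanobis:
    def test_identity_covariance_reduces_to_euclidean(self, small_epochs):
        cov = rm.ShrunkCovariance(np.eye(small_epochs.n_channels), 0.0)
        rdm = rm.mahalanobis_rdm(small_epochs, 100.0, cov)
        means = rm.condition_mean_topographies(small_epochs, 100.0)
        i, j = pair_indices()
        expected = np.linalg.norm(means[i] - means[j], axis=1)
        assert np.allclose(rdm[i, j], expected, atol=1e-10)

    def test_two_channel_worked_example(self):
        """Delta = (1, 0), Cov = diag(2, 1): MD = sqrt(1/2)."""
        delta = np.array([1.0, 0.0])
        cov = np.diag([2.0, 1.0])
        md = float(np.sqrt(delta @ np.linalg.inv(cov) @ delta))
        assert md == pytest.approx(np.sqrt(0.5), abs=1e-12)
        from rsamediate.rdm import _mahalanobis_from_means

        means = np.zeros((8, 2))
        means[0] = delta
        rdm = _mahalanobis_from_means(means, cov)
        assert rdm[0, 1] == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert rdm[1, 2] == 0.0

    def test_identical_topographies_give_zero(self):
        from rsamediate.rdm import _mahalanobis_from_means

        means = np.ones((8, 4))
        rdm = _mahalanobis_from_means(means, np.eye(4))
        assert np.all(rdm == 0)

    def test_channel_permutation_invariance(self, rng):
        from rsamediate.rdm import _mahalanobis_from_means

        means = rng.standard_normal((8, 5))
        a = rng.standard_normal((30, 5))
        cov = a.T @ a / 30 + 0.1 * np.eye(5)
        perm = rng.permutation(5)
        base = _mahalanobis_from_means(means, cov)
        permuted = _mahalanobis_from_means(means[:, perm], cov[np.ix_(perm, perm)])
        assert np.allclose(base, permuted, atol=1e-10)

    def test_scale_monotonicity(self, rng):
        from rsamediate.rdm import _mahalanobis_from_means

        means = rng.standard_normal((8, 4))
        cov = np.eye(4) * 2.0
        assert np.allclose(
            _mahalanobis_from_means(2 * means, cov),
            2 * _mahalanobis_from_means(means, cov),
            atol=1e-10,
        )

    def test_singular_covariance_rejected(self, small_epochs):
        cov_mat = np.zeros((small_epochs.n_channels, small_epochs.n_channels))
        cov = rm.ShrunkCovariance.__new__(rm.ShrunkCovariance)
        cov.matrix = cov_mat
        cov.shrinkage_intensity = 0.0
        with pytest.raises(rm.DegenerateDataError):
            rm.mahalanobis_rdm(small_epochs, 100.0, cov)

    def test_noise_free_single_dimension_matches_model_rdm(self):
        """With only race amplitude and no noise, the neural RDM at the race
        peak is rank-correlated 1 with the race model RDM."""
        cfg = rm.SimulationConfig(
            n_channels=12,
            trials_per_condition=1,
            dimension_amplitudes={"race": 1.5, "pain": 0.0, "gender": 0.0},
            noise_variance_uv2=0.0,
            seed=7,
        )
        ep = rm.simulate_participant_eeg(cfg, 1.0, seed=0)
        cov = rm.ShrunkCovariance(np.eye(12), 0.0)
        rdm = rm.mahalanobis_rdm(ep, 140.0, cov)
        i, j = pair_indices()
        model = rm.build_model_rdms().race
        rho = stats.spearmanr(rdm[i, j], model[i, j]).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)


class TestVectorize:
    def test_zscore_moments(self, rng):
        mat = devectorize(rng.standard_normal(28) ** 2)
        v = rm.vectorize_and_zscore(mat)
        assert v.shape == (28,)
        assert abs(v.mean()) < 1e-12
        assert v.std() == pytest.approx(1.0, abs=1e-12)

    @given(
        scale=st.floats(0.1, 50.0),
        offset=st.floats(-10.0, 10.0),
    )
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(5)
        mat = devectorize(rng.random(28) + 0.5)
        a = rm.vectorize_and_zscore(mat)
        b = rm.vectorize_and_zscore(scale * mat + offset * (1 - np.eye(8)))
        assert np.allclose(a, b, atol=1e-9)

    def test_round_trip_with_devectorizer(self, rng):
        vec = rng.standard_normal(28)
        mat = devectorize(vec)
        i, j = pair_indices()
        assert np.allclose(mat[i, j], vec)
        assert np.allclose(mat, mat.T)

    def test_constant_rdm_flagged(self):
        with pytest.raises(rm.DegenerateDataError):
            rm.vectorize_and_zscore(np.ones((8, 8)) - np.eye(8))


class TestSeries:
    def test_per_epoch_and_per_timepoint_modes(self, small_epochs):
        a = rm.neural_rdm_series(small_epochs, cov_mode="per_timepoint")
        b = rm.neural_rdm_series(small_epochs, cov_mode="per_epoch")
        assert a.rdms.shape == b.rdms.shape == (small_epochs.n_times, 8, 8)
        assert not np.allclose(a.rdms, b.rdms)
        sym = a.rdms - a.rdms.transpose(0, 2, 1)
        assert np.abs(sym).max() < 1e-10

    def test_single_timepoint_matches_public_op(self, small_epochs):
        series = rm.neural_rdm_series(small_epochs, cov_mode="per_timepoint")
        ti = small_epochs.time_index(140.0)
        idx = small_epochs.condition_index()
        means = np.stack(
            [small_epochs.data[idx == c, :, ti].mean(axis=0) for c in range(8)]
        )
        demeaned = small_epochs.data[:, :, ti] - means[idx]
        cov = rm.shrinkage_covariance(demeaned)
        single = rm.mahalanobis_rdm(small_epochs, 140.0, cov)
        assert np.allclose(series.rdms[ti], single, atol=1e-10)
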