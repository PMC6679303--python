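"""Tests of the ensemble Kalman filter against closed forms and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatda.enkf import (EnsembleMatrix, ObservationVector, StateVector,
                          analysis, ensemble_stats, forecast, kalman_gain,
                          perturb_observations, selection_matrix)


def scalar_ensemble(values, label="x"):
    return EnsembleMatrix(np.asarray(values, float)[:, None], (label,))


class TestEnsembleStats:
    def test_identical_members_zero_covariance(self):
        ens = EnsembleMatrix(np.full((5, 2), 3.0), ("LAI", "SM"))
        mean, cov = ensemble_stats(ens)
        assert np.allclose(mean.values, 3.0)
        assert np.allclose(cov, 0.0)

    def test_two_member_variance_uses_ne_minus_one(self):
        # members {0, 2}: mean 1, sample variance 2 with the 1/(Ne-1) divisor
        mean, cov = ensemble_stats(scalar_ensemble([0.0, 2.0]))
        assert mean.values[0] == pytest.approx(1.0)
        assert cov[0, 0] == pytest.approx(2.0)

    def test_large_sample_recovers_moments(self):
        rng = np.random.default_rng(5)
        mu = np.array([2.0, -1.0])
        sigma = np.array([[2.0, 0.6], [0.6, 1.0]])
        draws = rng.multivariate_normal(mu, sigma, size=1000)
        mean, cov = ensemble_stats(EnsembleMatrix(draws, ("a", "b")))
        assert np.allclose(mean.values, mu, atol=0.15)
        assert np.allclose(cov, sigma, rtol=0.10, atol=0.05)

    def test_member_permutation_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(40, 2))
        ens = EnsembleMatrix(data, ("a", "b"))
        perm = EnsembleMatrix(data[rng.permutation(40)], ("a", "b"))
        m1, c1 = ensemble_stats(ens)
        m2, c2 = ensemble_stats(perm)
        assert np.allclose(m1.values, m2.values)
        assert np.allclose(c1, c2)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            EnsembleMatrix(np.ones((1, 2)), ("a", "b"))


class TestForecast:
    def test_identity_zero_noise_is_noop(self):
        ens = scalar_ensemble([1.0, 2.0, 3.0])
        out = forecast(ens, lambda x: x, Q=np.zeros((1, 1)), rng_seed=0)
        assert np.array_equal(out.data, ens.data)

    def test_linear_propagator(self):
        ens = EnsembleMatrix(np.array([[1.0, 0.2], [2.0, 0.4]]),
                             ("LAI", "SM"))
        out = forecast(ens, lambda x: 2 * x, Q=None)
        assert np.allclose(out.data, 2 * ens.data)

    def test_noise_inflates_variance_by_q(self):
        ens = EnsembleMatrix(np.zeros((10_000, 1)), ("x",))
        out = forecast(ens, lambda x: x, Q=np.array([[0.5]]), rng_seed=11)
        assert out.data.var(ddof=1) == pytest.approx(0.5, rel=0.05)

    def test_non_psd_q_rejected(self):
        ens = scalar_ensemble([0.0, 1.0])
        with pytest.raises(ValueError):
            forecast(ens, lambda x: x, Q=np.array([[-1.0]]), rng_seed=0)


class TestPerturbObservations:
    def obs(self, r=0.04):
        return ObservationVector([2.0], ("LAI",), [r])

    def test_zero_variance_replicates_exactly(self):
        reps = perturb_observations(self.obs(r=0.0), 50, rng_seed=3)
        assert np.allclose(reps, 2.0)

    def test_replicate_variance_matches_r(self):
        reps = perturb_observations(self.obs(r=0.04), 10_000, rng_seed=3)
        assert reps.var(ddof=1) == pytest.approx(0.04, rel=0.05)

    def test_same_seed_reproduces(self):
        a = perturb_observations(self.obs(), 20, rng_seed=42)
        b = perturb_observations(self.obs(), 20, rng_seed=42)
        assert np.array_equal(a, b)


class TestKalmanGain:
    def test_scalar_closed_form(self):
        k = kalman_gain(np.array([[1.0]]), np.array([[1.0]]),
                        np.array([[1.0]]))
        assert abs(k[0, 0] - 0.5) < 1e-12

    def test_huge_observation_error_ignores_observation(self):
        k = kalman_gain(np.array([[1.0]]), np.array([[1.0]]),
                        np.array([[1e12]]))
        assert k[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_two_state_worked_example(self):
        # Pf = [[2,1],[1,1]], H = [1 0], r = 1:
        # K = Pf H' / (H Pf H' + r) = [2,1]'/3
        pf = np.array([[2.0, 1.0], [1.0, 1.0]])
        h = np.array([[1.0, 0.0]])
        k = kalman_gain(pf, h, np.array([[1.0]]))
        assert np.abs(k - np.array([[2 / 3], [1 / 3]])).max() < 1e-10

    def test_singular_innovation_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            kalman_gain(np.zeros((1, 1)), np.array([[1.0]]),
                        np.zeros((1, 1)))

    def test_scalar_gain_bounded(self):
        for p in (0.1, 1.0, 10.0):
            for r in (0.1, 1.0, 10.0):
                k = kalman_gain(np.array([[p]]), np.array([[1.0]]),
                                np.array([[r]]))[0, 0]
                assert 0.0 <= k <= 1.0


class TestSelectionMatrix:
    def test_selects_named_components(self):
        h = selection_matrix(("LAI", "SM"), ("SM",))
        assert np.array_equal(h, [[0.0, 1.0]])

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            selection_matrix(("LAI", "SM"), ("ET",))


class TestAnalysis:
    def make_ensemble(self, seed=0, ne=200):
        rng = np.random.default_rng(seed)
        data = rng.multivariate_normal([3.0, 0.25],
                                       [[0.4, 0.01], [0.01, 0.002]], size=ne)
        return EnsembleMatrix(data, ("LAI", "SM"))

    @pytest.mark.parametrize("mode", ["raw", "second_order"])
    def test_huge_r_leaves_ensemble_unchanged(self, mode):
        ens = self.make_ensemble()
        obs = ObservationVector([10.0], ("LAI",), [1e12])
        out = analysis(ens, obs, rng_seed=1, perturbation_mode=mode)
        assert np.allclose(out.data, ens.data, atol=1e-3)

    @pytest.mark.parametrize("mode", ["raw", "second_order"])
    def test_tiny_r_snaps_observed_component_to_observation(self, mode):
        ens = self.make_ensemble()
        obs = ObservationVector([5.0, 0.30], ("LAI", "SM"), [1e-12, 1e-12])
        out = analysis(ens, obs, rng_seed=1, perturbation_mode=mode)
        assert np.allclose(out.data[:, 0], 5.0, atol=1e-3)
        assert np.allclose(out.data[:, 1], 0.30, atol=1e-3)

    def test_mean_preserved_when_observation_equals_forecast_mean(self):
        ens = self.make_ensemble()
        mean, _ = ensemble_stats(ens)
        obs = ObservationVector([mean.values[0]], ("LAI",), [1e-8])
        out = analysis(ens, obs, rng_seed=2)
        new_mean, _ = ensemble_stats(out)
        assert new_mean.values[0] == pytest.approx(mean.values[0], abs=1e-4)

    def test_unobserved_component_moves_through_cross_covariance(self):
        ens = self.make_ensemble()
        obs = ObservationVector([5.0], ("LAI",), [0.01])
        out = analysis(ens, obs, rng_seed=3)
        _, pf = ensemble_stats(ens)
        mean, _ = ensemble_stats(ens)
        new_mean, _ = ensemble_stats(out)
        # SM moves in the direction of the positive cross-covariance
        assert new_mean.values[1] > mean.values[1]

    def test_second_order_posterior_variance_contracts_every_time(self):
        for seed in range(20):
            ens = self.make_ensemble(seed=seed, ne=50)
            _, pf = ensemble_stats(ens)
            obs = ObservationVector([3.5], ("LAI",), [0.2])
            out = analysis(ens, obs, rng_seed=seed)
            _, pa = ensemble_stats(out)
            assert pa[0, 0] <= pf[0, 0] * (1 + 1e-10)

    def test_gain_mask_blocks_cross_update(self):
        ens = self.make_ensemble()
        mean, _ = ensemble_stats(ens)
        obs = ObservationVector([5.0], ("LAI",), [0.01])
        mask = np.array([[1.0], [0.0]])
        out = analysis(ens, obs, rng_seed=3, gain_mask=mask)
        assert np.allclose(out.data[:, 1], ens.data[:, 1])

    def test_full_run_reproducible_from_seed(self):
        ens = self.make_ensemble()
        obs = ObservationVector([4.0, 0.2], ("LAI", "SM"), [0.1, 0.001])
        a = analysis(ens, obs, rng_seed=7)
        b = analysis(ens, obs, rng_seed=7)
        assert np.array_equal(a.data, b.data)


class TestLinearGaussianEquivalence:
    """EnKF vs the exact Kalman filter on a scalar linear-Gaussian system."""

    def test_matches_closed_form_kalman_filter(self):
        a, q, r = 0.9, 1.0, 1.0
        m0, p0 = 10.0, 4.0
        rng = np.random.default_rng(123)
        ne = 2000

        # truth and observations
        x = m0 + np.sqrt(p0) * rng.standard_normal()
        obs = []
        for _ in range(10):
            x = a * x + np.sqrt(q) * rng.standard_normal()
            obs.append(x + np.sqrt(r) * rng.standard_normal())

        # exact KF recursion (the independent oracle)
        m, p = m0, p0
        kf = []
        for y in obs:
            mf, pf = a * m, a * a * p + q
            k = pf / (pf + r)
            m, p = mf + k * (y - mf), (1 - k) * pf
            kf.append((m, p))

        # EnKF with an exact-moment initial ensemble
        draws = rng.standard_normal(ne)
        draws = (draws - draws.mean()) / draws.std(ddof=1)
        ens = EnsembleMatrix((m0 + np.sqrt(p0) * draws)[:, None], ("x",))
        for t, y in enumerate(obs):
            ens = forecast(ens, lambda v: a * v, Q=np.array([[q]]),
                           rng_seed=rng, noise_mode="second_order")
            ens = analysis(ens, ObservationVector([y], ("x",), [r]),
                           rng_seed=rng)
            mean, cov = ensemble_stats(ens)
            m_kf, p_kf = kf[t]
            assert mean.values[0] == pytest.approx(m_kf, rel=0.02)
            assert cov[0, 0] == pytest.approx(p_kf, rel=0.02)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_gain_between_zero_and_one_for_any_scalar_system(seed):
    rng = np.random.default_rng(seed)
    p, r = rng.uniform(1e-6, 10.0, size=2)
    k = kalman_gain(np.array([[p]]), np.array([[1.0]]), np.array([[r]]))
    assert 0.0 < k[0, 0] < 1.0
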