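"""Level randomization and the unbiased score/Hessian estimators."""

import numpy as np
import pytest

import podhess as ph
from podhess.unbiased import _rng, _run_level0
from conftest import THETA_OU

FAST = ph.EstimatorSettings(n_particles=16)


def _kalman_fd(model, theta, obs, level):
    return ph.fd_score_hessian(
        lambda t: ph.kalman_loglik(ph.discretized_linear_system(model, t, level), obs),
        np.asarray(theta, float),
    )


class TestLevelDistribution:
    def test_truncated_small_case(self):
        dist = ph.level_distribution("truncated", L=2)
        assert np.allclose(dist.pmf, [4 / 7, 2 / 7, 1 / 7])
        assert np.isclose(dist.tail(0), 1.0)
        assert np.isclose(dist.tail(2), 1 / 7)

    @pytest.mark.parametrize("mode", ["truncated", "constant_sigma", "nonconstant_sigma"])
    def test_tail_at_zero_is_one(self, mode):
        dist = ph.level_distribution(mode, L=5 if mode == "truncated" else None)
        assert np.isclose(dist.tail(0), 1.0)
        tails = dist.tail(np.arange(dist.max_level + 1))
        assert np.all(np.diff(tails) <= 1e-15)

    def test_constant_sigma_ratio(self):
        dist = ph.level_distribution("constant_sigma")
        ratio = dist.pmf[1] / dist.pmf[0]
        expected = (0.5 * 2 * np.log2(3.0) ** 2) / (1.0 * 1.0 * np.log2(2.0) ** 2)
        assert np.isclose(ratio, expected)
        assert np.isclose(ratio, 2.512, atol=5e-4)

    def test_negative_truncation_rejected(self):
        with pytest.raises(ValueError):
            ph.level_distribution("truncated", L=-1)

    def test_sampling_matches_pmf(self, rng):
        dist = ph.level_distribution("truncated", L=3)
        draws = dist.sample(rng, size=20000)
        freq = np.bincount(draws, minlength=4) / 20000
        assert np.allclose(freq, dist.pmf, atol=0.01)


class TestSingleTermEstimators:
    def test_xi_level0_matches_kalman_score(self, ou_model, ou_obs3):
        R = 3000
        acc, tau, capped = _run_level0(
            ou_model, THETA_OU.copy(), ou_obs3.values, R, FAST, _rng(3, 0)
        )
        sc, _ = _kalman_fd(ou_model, THETA_OU, ou_obs3, 0)
        se = acc["score"].std(axis=0) / np.sqrt(R)
        assert np.all(np.abs(acc["score"].mean(axis=0) - sc) < 3 * se)
        assert not capped.any()

    def test_xi_level_l_matches_kalman_difference(self, ou_model, ou_obs3):
        R = 2500
        inc, diag = ph.xi_functional_increments(
            ou_model, THETA_OU, ou_obs3, level=2, R=R, settings=FAST, seed=5
        )
        s2, _ = _kalman_fd(ou_model, THETA_OU, ou_obs3, 2)
        s1, _ = _kalman_fd(ou_model, THETA_OU, ou_obs3, 1)
        se = inc["score"].std(axis=0) / np.sqrt(R)
        assert np.all(np.abs(inc["score"].mean(axis=0) - (s2 - s1)) < 3 * se)

    def test_xi_single_replicate_api(self, ou_model, ou_obs2):
        est0 = ph.xi_level0(ou_model, THETA_OU, ou_obs2, settings=FAST, seed=1)
        assert est0.level == 0 and est0.xi_outer.shape == (2, 2)
        assert est0.meeting_times[0] >= 1 and not est0.truncated_flag
        est2 = ph.xi_level_l(ou_model, THETA_OU, ou_obs2, level=2, settings=FAST, seed=2)
        assert est2.level == 2 and len(est2.meeting_times) == 2
        assert np.allclose(est2.xi_outer, est2.xi_outer.T)

    def test_cap_flags_unmet_chains(self, ou_model, ou_obs2):
        tight = ph.EstimatorSettings(n_particles=2, cap=1 if False else 2)
        with pytest.warns(RuntimeWarning):
            est = ph.xi_level0(ou_model, THETA_OU, ou_obs2, settings=tight, seed=4)
        # with cap 2 and slow two-particle meeting, at least some runs flag
        # (this seed does); the estimate is still returned
        assert isinstance(est.truncated_flag, bool)

    def test_variance_decreases_with_level(self, ou_model, ou_obs2):
        # monotone trend of the score-increment variance over levels 1 and 4
        st = ph.EstimatorSettings(n_particles=64, m_star=3)
        v = []
        for l in (1, 4):
            inc, _ = ph.xi_functional_increments(
                ou_model, THETA_OU, ou_obs2, level=l, R=400, settings=st, seed=60 + l
            )
            v.append(inc["score"].var(axis=0).sum())
        assert v[1] < v[0]


class TestUnbiasedScore:
    def test_telescoping_to_fixed_level(self, ou_model, ou_obs3):
        # degenerate level pmf at 0 reduces to the level-0 estimator
        dist = ph.level_distribution("truncated", L=0)
        score, diag = ph.unbiased_score(
            ou_model, THETA_OU, ou_obs3, dist, settings=FAST, M=400, seed=8
        )
        sc, _ = _kalman_fd(ou_model, THETA_OU, ou_obs3, 0)
        se = diag["per_replicate"].std(axis=0) / np.sqrt(400)
        assert np.all(np.abs(score - sc) < 3.5 * se)

    def test_matches_high_level_kalman_score(self, ou_model, ou_obs3):
        dist = ph.level_distribution("truncated", L=5)
        score, diag = ph.unbiased_score(
            ou_model, THETA_OU, ou_obs3, dist, settings=FAST, M=800, seed=9
        )
        sc5, _ = _kalman_fd(ou_model, THETA_OU, ou_obs3, 5)
        se = diag["per_replicate"].std(axis=0) / np.sqrt(800)
        assert np.all(np.abs(score - sc5) < 3.5 * se)


class TestUnbiasedHessian:
    def test_drift_free_single_observation_information(self, ou_model):
        # with zero drift and one observation all Girsanov terms vanish and
        # the (variance, variance) entry reduces to the observation-only
        # information of the Gaussian model
        model = ph.with_fd_derivatives(
            ph.DiffusionModel(
                name="null", state_dim=1, param_dim=2, obs_dim=1,
                initial_state=[1.0], positivity_mask=[False, True],
                drift=lambda th, x: np.zeros_like(x),
                diffusion=lambda x: np.eye(1),
                diffusion_diag=np.ones(1),
                obs_logdensity=ou_model.obs_logdensity,
                psi_d2_zero=True,
            )
        )
        y = np.array([[1.4]])
        dist = ph.level_distribution("truncated", L=0)
        est = ph.unbiased_hessian(
            model, THETA_OU, y, dist, M=400, settings=FAST, seed=3
        )
        _, nh = _kalman_fd(ph.univariate_ou(), THETA_OU, ph.ObservationSeries(y), 0)
        # drift entries carry no information in this model
        assert abs(est.aggregate[0, 0]) < 0.2
        se = est.per_replicate.std(axis=0)[1, 1] / np.sqrt(400)
        # compare against the null-drift model's own Kalman information
        def ll(t):
            sys0 = ph.LinearGaussianSystem(
                M=np.eye(1), m=np.zeros(1), C=np.eye(1), R=t[1] * np.eye(1),
                x0=np.ones(1), steps_per_unit=1,
            )
            return ph.kalman_loglik(sys0, y)
        _, nh_null = ph.fd_score_hessian(ll, THETA_OU)
        assert abs(est.aggregate[1, 1] - nh_null[1, 1]) < 3.5 * se

    def test_matches_level5_kalman_information(self, ou_model, ou_obs3):
        dist = ph.level_distribution("truncated", L=5)
        est = ph.unbiased_hessian(
            ou_model, THETA_OU, ou_obs3, dist, M=600, settings=FAST, seed=11
        )
        _, nh5 = _kalman_fd(ou_model, THETA_OU, ou_obs3, 5)
        se = est.per_replicate.std(axis=0) / np.sqrt(600)
        assert np.all(np.abs(est.aggregate - nh5) < 3.5 * se)
        assert np.allclose(est.aggregate, est.aggregate.T)

    def test_replicate_independence_batched_means(self, ou_model, ou_obs2):
        dist = ph.level_distribution("truncated", L=2)
        est = ph.unbiased_hessian(
            ou_model, THETA_OU, ou_obs2, dist, M=400, settings=FAST, seed=13
        )
        half1 = est.per_replicate[:200].mean(axis=0)
        half2 = est.per_replicate[200:].mean(axis=0)
        spread = est.per_replicate.std(axis=0) * np.sqrt(1 / 200 + 1 / 200)
        assert np.all(np.abs(half1 - half2) < 4 * spread)

    def test_independent_product_stacks_remove_squared_bias(self, ou_model, ou_obs2):
        # the product term must multiply two INDEPENDENT stack sums: squaring
        # a single stack inflates the product by its own variance, which is
        # detectable on the score mean-square
        dist = ph.level_distribution("truncated", L=0)
        R = 1500
        acc1, _, _ = _run_level0(
            ou_model, THETA_OU.copy(), ou_obs2.values, R, FAST, _rng(17, 1)
        )
        acc2, _, _ = _run_level0(
            ou_model, THETA_OU.copy(), ou_obs2.values, R, FAST, _rng(17, 2)
        )
        s1, s2 = acc1["score"][:, 0], acc2["score"][:, 0]
        sc, _ = _kalman_fd(ou_model, THETA_OU, ou_obs2, 0)
        target = sc[0] ** 2
        indep = np.mean(s1 * s2)
        shared = np.mean(s1 * s1)
        se = np.std(s1 * s2) / np.sqrt(R)
        assert abs(indep - target) < 4 * se
        assert shared - target > 4 * se  # biased upward by Var(pi_hat)


class TestHessianIncrement:
    def test_increment_sample_shapes_and_symmetry(self, ou_model, ou_obs2):
        inc, diag = ph.hessian_increment_sample(
            ou_model, THETA_OU, ou_obs2, level=1, R=50, settings=FAST, seed=2
        )
        assert inc.shape == (50, 2, 2)
        assert np.allclose(inc, inc.swapaxes(-1, -2))
        assert diag["capped_fraction"] == 0.0
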