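"""Sweeps, optimizers and slope fitting."""

import numpy as np
import pytest

import podhess as ph
from conftest import THETA_OU


class TestSlopeFit:
    def test_recovers_known_power_law(self):
        steps = 0.5 ** np.arange(1, 7)
        vals = 3.0 * steps**1.3
        slope, se, intercept = ph.fit_loglog_slope(steps, vals)
        assert np.isclose(slope, 1.3)
        assert se < 1e-12


class TestBiasSweep:
    def test_level_insensitive_model_has_flat_bias(self, ou_model):
        # constant drift, linear in theta, constant sigma: the Euler
        # transition over a unit interval is level-independent, so the
        # discretized likelihood and hence the estimator's target do not
        # move with the level; the fine and coarse chains produce identical
        # output laws and the increments vanish
        model = ph.with_fd_derivatives(
            ph.DiffusionModel(
                name="const", state_dim=1, param_dim=2, obs_dim=1,
                initial_state=[0.0], positivity_mask=[False, True],
                drift=lambda th, x: np.full_like(x, th[0]),
                diffusion=lambda x: np.eye(1),
                diffusion_diag=np.ones(1),
                obs_logdensity=ou_model.obs_logdensity,
                psi_d2_zero=False,
            )
        )
        obs = ph.simulate_observations(model, [0.3, 0.38], n=4, sim_level=3, seed=2)
        inc, _ = ph.xi_functional_increments(
            model, [0.3, 0.38], obs, level=2, R=30,
            settings=ph.EstimatorSettings(n_particles=16), seed=7,
        )
        # bit-exact zero increments: fine and coarse systems coincide
        assert np.allclose(inc["score"], 0.0, atol=1e-10)
        assert np.allclose(inc["hess"], 0.0, atol=1e-10)

    def test_ou_bias_decays_toward_exact_reference(self, ou_model):
        # small configuration: the estimated level-L information must drift
        # toward the exact-transition Kalman reference as L grows
        obs = ph.simulate_observations(ou_model, THETA_OU, n=10, sim_level=10, seed=3)
        res = ph.bias_sweep(
            ou_model, THETA_OU, obs, levels=[1, 4], M=300,
            settings=ph.EstimatorSettings(n_particles=64, m_star=3), seed=5,
        )
        assert res.summary[1] < res.summary[0]


class TestVarianceSweep:
    def test_level_insensitive_increments_have_zero_variance(self, ou_model):
        # constant drift + constant sigma: functionals depend on the path
        # only through level-independent sums, fine and coarse systems stay
        # bit-identical at shared grid points, and every increment is
        # exactly zero -- so its sample variance is zero at every level
        model = ph.with_fd_derivatives(
            ph.DiffusionModel(
                name="const", state_dim=1, param_dim=2, obs_dim=1,
                initial_state=[0.0], positivity_mask=[False, True],
                drift=lambda th, x: np.full_like(x, th[0]),
                diffusion=lambda x: np.eye(1),
                diffusion_diag=np.ones(1),
                obs_logdensity=ou_model.obs_logdensity,
            )
        )
        obs = ph.simulate_observations(model, [0.3, 0.38], n=3, sim_level=3, seed=2)
        for level in (1, 3):
            inc, _ = ph.xi_functional_increments(
                model, [0.3, 0.38], obs, level=level, R=25,
                settings=ph.EstimatorSettings(n_particles=8), seed=6 + level,
            )
            assert np.allclose(inc["hess"].var(axis=0), 0.0, atol=1e-16)

    def test_variance_sweep_runs_and_reports(self, ou_model):
        obs = ph.simulate_observations(ou_model, THETA_OU, n=5, sim_level=8, seed=4)
        res = ph.increment_variance_sweep(
            ou_model, THETA_OU, obs, levels=[1, 2, 3], reps=60,
            settings=ph.EstimatorSettings(n_particles=32), seed=9,
        )
        assert res.summary.shape == (3,)
        assert np.all(res.summary > 0)
        assert np.isfinite(res.slope)


class TestSgd:
    def test_zero_gradient_stub_keeps_iterates_constant(self, ou_model):
        trace = ph.sgd_optimize(
            ou_model, np.array([[0.5]]), [0.3, 0.3], rate=0.01,
            theta_true=[0.46, 0.38], max_iter=5,
            score_fn=lambda th, k: np.zeros(2),
        )
        assert np.allclose(trace.thetas, trace.thetas[0])
        assert trace.converged_at is None

    def test_exact_score_converges_to_mle(self, ou_model):
        # Kalman-exact gradient ascent reaches the maximizer found by direct
        # numerical optimization of the same likelihood
        from scipy import optimize

        obs = ph.simulate_observations(ou_model, THETA_OU, n=40, sim_level=8, seed=6)

        def ll(t):
            return ph.kalman_loglik(ph.discretized_linear_system(ou_model, t, 2), obs)

        opt = optimize.minimize(
            lambda t: -ll(t), x0=[0.3, 0.3], bounds=[(0.01, 3), (0.01, 3)]
        )
        def exact_score(th, k):
            s, _ = ph.fd_score_hessian(ll, th)
            return s

        trace = ph.sgd_optimize(
            ou_model, obs, [0.1, 0.1], rate=0.002, theta_true=opt.x,
            max_iter=4000, tol=0.02, score_fn=exact_score,
        )
        assert trace.converged_at is not None

    def test_rejects_nonpositive_rate(self, ou_model):
        with pytest.raises(ValueError):
            ph.sgd_optimize(
                ou_model, np.array([[0.5]]), [0.3, 0.3], rate=0.0,
                theta_true=[0.46, 0.38],
            )


class TestNewton:
    def test_one_step_on_quadratic(self):
        A = np.array([[2.0, 0.0], [0.0, 3.0]])
        target = np.array([0.5, 0.5])

        trace = ph.newton_optimize(
            ph.univariate_ou(), np.array([[0.5]]), [0.1, 0.1],
            theta_true=target, variant="full", max_iter=3, tol=1e-8,
            score_fn=lambda th, k: A @ (target - th),
            hessian_fn=lambda th, k: A,
        )
        assert trace.converged_at == 1

    def test_modified_step_arithmetic(self):
        # diagonal (2, 2) estimate with ridge 1e-4 and score (1, 1): the
        # full step is 1/2.0001 per component while the score norm exceeds
        # the gate
        captured = []

        def hess_fn(th, k):
            return 2.0 * np.eye(2)

        def score_fn(th, k):
            captured.append(th.copy())
            return np.ones(2)

        trace = ph.newton_optimize(
            ph.univariate_ou(), np.array([[0.5]]), [0.1, 0.1],
            theta_true=[10.0, 10.0], variant="modified", max_iter=1, tol=1e-9,
            score_fn=score_fn, hessian_fn=hess_fn,
        )
        step = trace.thetas[1] - trace.thetas[0]
        assert np.allclose(step, 1.0 / 2.0001, atol=1e-9)

    def test_exact_newton_converges_fast(self, ou_model):
        obs = ph.simulate_observations(ou_model, THETA_OU, n=40, sim_level=8, seed=6)

        def ll(t):
            return ph.kalman_loglik(ph.discretized_linear_system(ou_model, t, 2), obs)

        from scipy import optimize

        opt = optimize.minimize(
            lambda t: -ll(t), x0=[0.3, 0.3], bounds=[(0.01, 3), (0.01, 3)]
        )

        def fd(th, k):
            return ph.fd_score_hessian(ll, th)

        trace = ph.newton_optimize(
            ou_model, obs, [0.1, 0.1], theta_true=opt.x, variant="full",
            max_iter=10, tol=0.02,
            score_fn=lambda th, k: fd(th, k)[0],
            hessian_fn=lambda th, k: fd(th, k)[1],
        )
        assert trace.converged_at is not None and trace.converged_at <= 10

    def test_singular_hessian_advises_modified_variant(self, ou_model):
        with pytest.raises(np.linalg.LinAlgError):
            ph.newton_optimize(
                ou_model, np.array([[0.5]]), [0.1, 0.1], theta_true=[5.0, 5.0],
                variant="full", max_iter=2,
                score_fn=lambda th, k: np.ones(2),
                hessian_fn=lambda th, k: np.zeros((2, 2)),
            )


class TestFullScaleConfigs:
    def test_study_configurations_parse_with_printed_values(self):
        import pathlib

        import yaml

        root = pathlib.Path(__file__).resolve().parents[1] / "configs"
        ou = yaml.safe_load((root / "ou1d_full.yaml").read_text())
        assert ou["theta_true"] == [0.46, 0.38]
        assert ou["n_observations"] == 500
        assert ou["experiments"]["bias_sweep"]["replicates"] == 10000
        assert ou["experiments"]["sgd"]["learning_rate"] == 0.002
        mv = yaml.safe_load((root / "mvou_full.yaml").read_text())
        assert mv["theta_true"] == [0.48, 0.78, 0.37, 0.32]
        assert mv["sigma"] == [0.8, 0.6]
        assert mv["experiments"]["sgd"]["learning_rate"] == 0.005
        fhn = yaml.safe_load((root / "fhn_full.yaml").read_text())
        assert fhn["theta_true"] == [0.89, 0.98, 0.5, 0.79]
        assert fhn["sim_level"] == 10
        assert fhn["experiments"]["variance_sweep"]["replicates"] == 1000
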