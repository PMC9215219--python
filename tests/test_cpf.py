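"""Conditional particle filter kernels, couplings, coalescence."""

import numpy as np
import pytest
from scipy import stats

import podhess as ph
from podhess.cpf import _maximal_indices_batch
from podhess.euler import simulate_prior_path
from conftest import THETA_OU


def _prior_path(model, theta, n, level, seed):
    rng = np.random.default_rng(seed)
    return ph.LatticePath(level, simulate_prior_path(model, theta, n, level, rng))


class TestIndexCouplings:
    def test_maximal_identical_pmfs_always_meet(self):
        r = np.array([0.2, 0.3, 0.5])
        for s in range(50):
            i, j = ph.maximal_coupling_indices(r, r, seed=s)
            assert i == j

    def test_maximal_meeting_probability_half(self):
        r = np.array([0.5, 0.5])
        rb = np.array([1.0, 0.0])
        hits = sum(
            ph.maximal_coupling_indices(r, rb, seed=s)[0]
            == ph.maximal_coupling_indices(r, rb, seed=s)[1]
            for s in range(4000)
        )
        # sum_m min = 0.5; binomial 3-sigma band
        assert abs(hits / 4000 - 0.5) < 3 * 0.5 / np.sqrt(4000)

    def test_maximal_marginals_and_overlap(self):
        r = np.array([0.7, 0.3])
        rb = np.array([0.4, 0.6])
        draws = np.array(
            [ph.maximal_coupling_indices(r, rb, seed=s) for s in range(20000)]
        )
        meet = np.mean(draws[:, 0] == draws[:, 1])
        assert abs(meet - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 20000)
        assert abs(np.mean(draws[:, 0] == 0) - 0.7) < 0.02
        assert abs(np.mean(draws[:, 1] == 0) - 0.4) < 0.02

    def test_inversion_identical_pmfs_always_meet(self, rng):
        r = np.array([0.25, 0.25, 0.5])
        for _ in range(100):
            i, j = ph.inversion_coupling_indices(r, r, rng.random())
            assert i == j

    def test_inversion_hand_computed_case(self):
        assert ph.inversion_coupling_indices([0.5, 0.5], [0.7, 0.3], 0.6) == (1, 0)

    def test_inversion_marginals_preserved(self, rng):
        r = np.array([0.1, 0.6, 0.3])
        rb = np.array([0.3, 0.3, 0.4])
        us = rng.random(20000)
        draws = np.array([ph.inversion_coupling_indices(r, rb, u) for u in us])
        for k in range(3):
            assert abs(np.mean(draws[:, 0] == k) - r[k]) < 0.015
            assert abs(np.mean(draws[:, 1] == k) - rb[k]) < 0.015

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ph.maximal_coupling_indices([-0.1, 1.1], [0.5, 0.5])

    def test_batched_four_way_marginals(self, rng):
        # the hierarchical four-way coupling must leave each marginal intact
        w = np.array([
            [0.5, 0.3, 0.15, 0.05],
            [0.4, 0.35, 0.2, 0.05],
            [0.45, 0.3, 0.2, 0.05],
            [0.35, 0.4, 0.15, 0.1],
        ])[None]  # (1, 4, 4)
        W = np.repeat(w, 30000, axis=0)
        idx = _maximal_indices_batch(W, 1, rng)[:, :, 0]  # (R, 4)
        for s in range(4):
            for k in range(4):
                assert abs(np.mean(idx[:, s] == k) - w[0, s, k]) < 0.012


class TestCpfKernel:
    def test_single_particle_returns_reference(self, ou_model, ou_obs2):
        ref = _prior_path(ou_model, THETA_OU, 2, 0, seed=3)
        out = ph.cpf_kernel(ou_model, THETA_OU, ou_obs2, ref, N=1, seed=0)
        assert out == ref

    def test_near_noiseless_observation_pins_output(self, ou_model):
        # with near-zero observation variance, a reference trajectory pinned
        # to the data dominates every weight and is returned unchanged
        theta = np.array([0.46, 1e-8])
        y = np.array([[0.9], [0.7]])
        pinned = ph.LatticePath(0, np.array([[1.0], [0.9], [0.7]]))
        for s in range(5):
            out = ph.cpf_kernel(ou_model, theta, y, pinned, N=64, seed=s)
            assert out == pinned

    def test_invariance_against_quadrature_smoother(self, ou_model, ou_obs2):
        # long-run chain average of the smoothed latent state matches dense
        # quadrature within 3 standard errors (effective sample corrected)
        mom = ph.quadrature_smoother(ou_model, THETA_OU, ou_obs2, level=0)
        # smoothed mean of x_1 via a quadrature of the identity functional
        from podhess.oracles import _quadrature_moments

        rng = np.random.default_rng(0)
        cur = _prior_path(ou_model, THETA_OU, 2, 0, seed=11)
        xs = []
        for m in range(3000):
            cur = ph.cpf_kernel(
                ou_model, THETA_OU, ou_obs2, cur, N=8, seed=int(rng.integers(2**31))
            )
            xs.append(cur.values[1, 0])
        xs = np.asarray(xs[100:])
        # quadrature smoothed mean of x_1
        import numpy as _np

        grid = _np.linspace(-4, 4, 401)
        x1, x2 = _np.meshgrid(grid, grid, indexing="ij")
        v = THETA_OU[1]
        logw = (
            stats.norm.logpdf(x1, loc=1.0 - 0.46 * 1.0, scale=1.0)
            + stats.norm.logpdf(x2, loc=x1 - 0.46 * x1, scale=1.0)
            + stats.norm.logpdf(ou_obs2.values[0, 0], loc=x1, scale=_np.sqrt(v))
            + stats.norm.logpdf(ou_obs2.values[1, 0], loc=x2, scale=_np.sqrt(v))
        )
        w = _np.exp(logw - logw.max())
        w /= w.sum()
        target = (w * x1).sum()
        ess = len(xs) / (1 + 2 * 10)  # conservative autocorrelation allowance
        se = xs.std() / _np.sqrt(ess)
        assert abs(xs.mean() - target) < 3 * se


class TestDrivingCcpf:
    def test_equal_frozen_pair_faithful(self, ou_model, ou_obs2):
        ref = _prior_path(ou_model, THETA_OU, 2, 0, seed=2)
        z = ph.CoupledPairState(ref, ref)
        sys1, sys2, (p1, p2) = ph.driving_ccpf(
            ou_model, THETA_OU, ou_obs2, z, N=16, seed=9
        )
        assert p1 == p2
        assert np.array_equal(sys1.trajectories, sys2.trajectories)

    def test_marginal_output_distribution_matches_cpf(self, ou_model, ou_obs2):
        # first coordinate of the coupled kernel vs the plain CPF kernel,
        # started from the same reference: same law of the smoothed endpoint
        ref = _prior_path(ou_model, THETA_OU, 2, 0, seed=2)
        refb = _prior_path(ou_model, THETA_OU, 2, 0, seed=3)
        z = ph.CoupledPairState(ref, refb)
        coupled, single = [], []
        for s in range(800):
            _, _, (p1, _) = ph.driving_ccpf(
                ou_model, THETA_OU, ou_obs2, z, N=8, seed=s
            )
            coupled.append(p1.values[-1, 0])
            out = ph.cpf_kernel(ou_model, THETA_OU, ou_obs2, ref, N=8, seed=10_000 + s)
            single.append(out.values[-1, 0])
        _, p = stats.ks_2samp(coupled, single)
        assert p > 1e-3


class TestCcpfKernel:
    def test_equal_inputs_give_equal_outputs(self, ou_model, ou_obs2):
        ref = _prior_path(ou_model, THETA_OU, 2, 0, seed=4)
        z = ph.CoupledPairState(ref, ref)
        out = ph.ccpf_kernel(ou_model, THETA_OU, ou_obs2, z, N=16, seed=1)
        assert out.coalesced

    def test_coalescence_is_absorbing(self, ou_model, ou_obs3):
        z = ph.init_pair(ou_model, THETA_OU, ou_obs3, N=16, seed=6)
        met_at = None
        for m in range(200):
            z = ph.ccpf_kernel(ou_model, THETA_OU, ou_obs3, z, N=16, seed=100 + m)
            if z.coalesced:
                met_at = m
                break
        assert met_at is not None
        for m in range(50):
            z = ph.ccpf_kernel(ou_model, THETA_OU, ou_obs3, z, N=16, seed=7000 + m)
            assert z.coalesced

    def test_two_chain_invariance_small_model(self, ou_model, ou_obs2):
        # marginal long-run average of the second chain's smoothed score
        # matches the quadrature smoother
        mom = ph.quadrature_smoother(ou_model, THETA_OU, ou_obs2, level=0)
        rng = np.random.default_rng(3)
        z = ph.init_pair(ou_model, THETA_OU, ou_obs2, N=8, seed=1)
        vals = []
        for m in range(2500):
            z = ph.ccpf_kernel(
                ou_model, THETA_OU, ou_obs2, z, N=8, seed=int(rng.integers(2**31))
            )
            vals.append(
                ph.score_functional(ou_model, THETA_OU, z.first, ou_obs2)
            )
        vals = np.asarray(vals[100:])
        ess = len(vals) / 20
        se = vals.std(axis=0) / np.sqrt(ess)
        assert np.all(np.abs(vals.mean(axis=0) - mom.mean_score) < 3 * se)


class TestInitPair:
    def test_seed_reproducibility(self, ou_model, ou_obs2):
        a = ph.init_pair(ou_model, THETA_OU, ou_obs2, N=8, seed=12)
        b = ph.init_pair(ou_model, THETA_OU, ou_obs2, N=8, seed=12)
        assert a.first == b.first and a.second == b.second

    def test_second_coordinate_is_prior_draw(self, ou_model, ou_obs2, rng):
        # the frozen coordinate's law is the Euler prior (never conditioned)
        ends = [
            ph.init_pair(ou_model, THETA_OU, ou_obs2, N=8, seed=s).second.values[-1, 0]
            for s in range(1500)
        ]
        direct = simulate_prior_path(
            ou_model, THETA_OU, 2, 0, rng, shape=(1500,)
        )[:, -1, 0]
        _, p = stats.ks_2samp(ends, direct)
        assert p > 1e-3

    def test_zero_diffusion_prior_is_deterministic_flow(self, ou_model):
        model = ph.DiffusionModel(
            name="det", state_dim=1, param_dim=2, obs_dim=1,
            initial_state=[1.0], positivity_mask=[False, True],
            drift=lambda th, x: -th[0] * x,
            diffusion=lambda x: np.zeros((1, 1)),
            diffusion_diag=np.zeros(1),
            obs_logdensity=ou_model.obs_logdensity,
            psi_d2_zero=True,
        )
        y = np.array([[0.6], [0.3]])
        z = ph.init_pair(model, THETA_OU, y, N=4, seed=0)
        flow = [1.0, 1.0 * 0.54, 1.0 * 0.54**2]
        assert np.allclose(z.second.values[:, 0], flow)
        assert np.allclose(z.first.values[:, 0], flow)  # all particles coincide
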