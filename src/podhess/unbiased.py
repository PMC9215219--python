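"""Randomized-level debiasing: single-term estimators and the unbiased Hessian.

The bias of the level-l discretized smoother is removed in two stages:

* within a level, a coupled chain started from the smoother's own kernel
  gives the unbiased single-term estimator
  ``pi_hat(F) = F(X(m*)) + sum_{m > m*}^{tau - 1} [F(X(m)) - F(X_bar(m))]``,
  whose correction sum terminates at the coalescence time tau;
* across levels, an independent level L is drawn from a pmf P_L and the level
  increments Xi^l = pi_hat^l - pi_hat^{l-1} for l <= L are weighted by the
  inverse tail probabilities 1/P_bar_L(l) (randomized multilevel debiasing).

The Hessian estimator assembles, per replicate, the three smoothed moments
of the score, score outer-product and Hessian path functionals; the product
of smoothed means uses a second, independent chain stack so that the product
of two unbiased estimators is unbiased for the product of expectations.

All drivers run batches of independent replicate chains simultaneously; the
batch is the outermost vectorized axis of every particle operation, which is
what keeps the many-replicate experiments tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .cpf import DEFAULT_N_PARTICLES, _obs_array, _sweep
from .euler import (
    LatticePath,
    simulate_prior_path,
    simulate_prior_path_two_level,
)
from .functionals import evaluate_path_functionals
from .models import DiffusionModel, _theta_array

__all__ = [
    "LevelDistribution",
    "level_distribution",
    "EstimatorSettings",
    "IncrementEstimate",
    "HessianEstimate",
    "xi_level0",
    "xi_level_l",
    "unbiased_score",
    "unbiased_hessian",
    "xi_functional_increments",
    "hessian_increment_sample",
]

# memory ceiling for one batched sweep's segment storage; drivers chunk the
# replicate axis to stay under it
_SEGMENT_BYTES_BUDGET = 2.5e8


@dataclass(frozen=True)
class LevelDistribution:
    """A positive pmf P_L on levels 0..max_level with exact tail sums."""

    pmf: np.ndarray
    mode: str
    truncation: Optional[int] = None

    def __post_init__(self):
        p = np.asarray(self.pmf, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("pmf must be non-negative and sum to one")
        object.__setattr__(self, "pmf", p)

    @property
    def max_level(self) -> int:
        return self.pmf.size - 1

    def tail(self, l) -> np.ndarray:
        """P_bar_L(l) = sum_{p >= l} P_L(p); tail(0) = 1 exactly."""
        tails = np.concatenate([np.cumsum(self.pmf[::-1])[::-1], [0.0]])
        return tails[np.asarray(l)]

    def sample(self, rng, size=None):
        return rng.choice(self.pmf.size, size=size, p=self.pmf)


def level_distribution(
    mode: str, L: Optional[int] = None, max_level: int = 40
) -> LevelDistribution:
    """Build the level pmf used by the randomized estimator.

    ``truncated``: P_L(l) proportional to Delta_l on {0..L} (requires L).
    ``constant_sigma``: proportional to Delta_l (l+1) log2(2+l)^2, the finite
    variance choice for constant diffusion coefficients.
    ``nonconstant_sigma``: proportional to Delta_l^{1/2} (l+1) log2(2+l)^2.
    The unbounded modes are normalized on 0..max_level for sampling.
    """
    if mode == "truncated":
        if L is None:
            raise ValueError("truncated mode requires a truncation level L")
        if L < 0:
            raise ValueError("truncation level must be >= 0")
        ls = np.arange(L + 1)
        raw = 0.5**ls
        return LevelDistribution(raw / raw.sum(), mode, truncation=int(L))
    ls = np.arange(max_level + 1)
    poly = (ls + 1) * np.log2(2.0 + ls) ** 2
    if mode == "constant_sigma":
        raw = 0.5**ls * poly
    elif mode == "nonconstant_sigma":
        raw = 0.5 ** (0.5 * ls) * poly
    else:
        raise ValueError(f"unknown level distribution mode {mode!r}")
    return LevelDistribution(raw / raw.sum(), mode)


@dataclass(frozen=True)
class EstimatorSettings:
    """Tunables shared by every coupled-chain estimator."""

    n_particles: int = DEFAULT_N_PARTICLES
    m_star: int = 2  # burn-in; the smallest admissible value
    cap: int = 10_000  # hard bound on kernel sweeps before flagging
    coupling: str = "maximal"
    # average the path functionals over the final particle cloud instead of
    # evaluating them on the single drawn trajectory (same expectation,
    # far smaller variance)
    rao_blackwellize: bool = True

    def __post_init__(self):
        if self.m_star < 2:
            raise ValueError("m_star must be >= 2")
        if self.n_particles < 2:
            raise ValueError("coupled estimators need at least two particles")


@dataclass(frozen=True)
class IncrementEstimate:
    """Xi^l for all tracked functionals, with meeting-time diagnostics."""

    level: int
    xi_score: np.ndarray  # (d_theta,)
    xi_outer: np.ndarray  # (d_theta, d_theta)
    xi_hess: np.ndarray  # (d_theta, d_theta)
    meeting_times: Tuple[int, ...]
    truncated_flag: bool


@dataclass(frozen=True)
class HessianEstimate:
    """Replicate-wise and aggregated unbiased Hessian estimates."""

    per_replicate: np.ndarray  # (M, d_theta, d_theta)
    aggregate: np.ndarray  # (d_theta, d_theta) arithmetic mean
    levels: np.ndarray  # (M,) primary-stack level draws L_k
    levels_tilde: np.ndarray  # (M,) independent-stack draws L~_k
    meeting_time_max: int
    capped_fraction: float
    # lower-variance assembly of the same M replicates: the mean-score
    # product uses the means of the two independent stacks, which is also
    # exactly unbiased but avoids per-replicate products of heavy tails
    aggregate_product_of_means: np.ndarray = None


# ---------------------------------------------------------------------------
# Batched coalescing-chain drivers
# ---------------------------------------------------------------------------


def _functionals(model, theta, values, level, y, order):
    """Evaluate (score[, outer, hess]) on a batch of stacked paths."""
    vals = evaluate_path_functionals(model, theta, values, y, level=level, order=order)
    if order == 1:
        return {"score": vals.score}
    return {"score": vals.score, "outer": vals.score_outer, "hess": vals.hess_fun}


def _chunk_sizes(R, n, n_systems, N, spu_f, d):
    per_chain = n * n_systems * N * spu_f * d * 8.0 * 1.5
    chunk = max(1, int(_SEGMENT_BYTES_BUDGET / per_chain))
    out = []
    start = 0
    while start < R:
        out.append((start, min(R, start + chunk)))
        start = out[-1][1]
    return out


def _run_level0(model, theta, y, R, settings, rng, order=2):
    """R independent CCPF chains at level 0; returns pi_hat moments per replicate."""
    n = y.shape[0]
    d = model.state_dim
    d_th = model.param_dim
    keys = ["score"] if order == 1 else ["score", "outer", "hess"]
    shapes = {"score": (d_th,), "outer": (d_th, d_th), "hess": (d_th, d_th)}
    acc = {k: np.zeros((R,) + shapes[k]) for k in keys}
    tau = np.zeros(R, dtype=np.int64)
    capped = np.zeros(R, dtype=bool)

    rb_order = order if settings.rao_blackwellize else 0
    for lo, hi in _chunk_sizes(R, n, 2, settings.n_particles, 1, d):
        Rc = hi - lo
        xp = simulate_prior_path(model, theta, n, 0, rng, shape=(Rc,))
        xbp = simulate_prior_path(model, theta, n, 0, rng, shape=(Rc,))
        outs, _, _, _ = _sweep(
            model, theta, y, [xp], [0], settings.n_particles, rng,
            coupling=settings.coupling,
        )
        X, Xb = outs[0], xbp
        ids = np.arange(Rc)
        m = 0
        while ids.size:
            m += 1
            if m > settings.cap:
                capped[lo + ids] = True
                warnings.warn(
                    f"level-0 chain cap {settings.cap} reached for {ids.size} replicates",
                    RuntimeWarning,
                )
                break
            outs, _, _, rb = _sweep(
                model, theta, y, [X, Xb], [0, 0], settings.n_particles, rng,
                coupling=settings.coupling,
                track_order=rb_order if m >= settings.m_star else 0,
            )
            X, Xb = outs
            met = np.all(X == Xb, axis=(1, 2))
            newly = met & (tau[lo + ids] == 0)
            tau[lo + ids[newly]] = m
            if m >= settings.m_star:
                if rb is not None:
                    f = {k: rb[k] for k in keys}  # (Rc, 2, ...)
                else:
                    fv = _functionals(
                        model, theta, np.stack([X, Xb], axis=1), 0, y, order
                    )
                    f = fv
                for k in keys:
                    if m == settings.m_star:
                        acc[k][lo + ids] += f[k][:, 0]
                    else:
                        acc[k][lo + ids] += f[k][:, 0] - f[k][:, 1]
            done = met & (m >= settings.m_star)
            if np.any(done):
                keep = ~done
                ids = ids[keep]
                X, Xb = X[keep], Xb[keep]
    return acc, tau, capped


def _run_level_l(model, theta, y, level, R, settings, rng, order=2):
    """R independent C-CCPF chains at levels (l, l-1); pi_hat per level."""
    if level < 1:
        raise ValueError("two-level chains require level >= 1")
    n = y.shape[0]
    d = model.state_dim
    d_th = model.param_dim
    N = settings.n_particles
    keys = ["score"] if order == 1 else ["score", "outer", "hess"]
    shapes = {"score": (d_th,), "outer": (d_th, d_th), "hess": (d_th, d_th)}
    acc_f = {k: np.zeros((R,) + shapes[k]) for k in keys}
    acc_c = {k: np.zeros((R,) + shapes[k]) for k in keys}
    tau_f = np.zeros(R, dtype=np.int64)
    tau_c = np.zeros(R, dtype=np.int64)
    capped = np.zeros(R, dtype=bool)
    levels4 = [level, level, level - 1, level - 1]

    rb_order = order if settings.rao_blackwellize else 0
    for lo, hi in _chunk_sizes(R, n, 4, N, 2**level + 2 ** (level - 1), d):
        Rc = hi - lo
        xf, xc = simulate_prior_path_two_level(model, theta, n, level, rng, shape=(Rc,))
        xbf, xbc = simulate_prior_path_two_level(model, theta, n, level, rng, shape=(Rc,))
        outs, _, _, _ = _sweep(
            model, theta, y, [xf, xc], [level, level - 1], N, rng,
            coupling=settings.coupling,
        )
        Xf, Xc, Xbf, Xbc = outs[0], outs[1], xbf, xbc
        ids = np.arange(Rc)
        m = 0
        while ids.size:
            m += 1
            if m > settings.cap:
                capped[lo + ids] = True
                warnings.warn(
                    f"level-{level} chain cap {settings.cap} reached for "
                    f"{ids.size} replicates",
                    RuntimeWarning,
                )
                break
            outs, _, _, rb = _sweep(
                model, theta, y, [Xf, Xbf, Xc, Xbc], levels4, N, rng,
                coupling=settings.coupling,
                track_order=rb_order if m >= settings.m_star else 0,
            )
            Xf, Xbf, Xc, Xbc = outs
            met_f = np.all(Xf == Xbf, axis=(1, 2))
            met_c = np.all(Xc == Xbc, axis=(1, 2))
            for met, tau in ((met_f, tau_f), (met_c, tau_c)):
                newly = met & (tau[lo + ids] == 0)
                tau[lo + ids[newly]] = m
            if m >= settings.m_star:
                if rb is not None:
                    ff = {k: rb[k][:, :2] for k in keys}
                    fc = {k: rb[k][:, 2:] for k in keys}
                else:
                    ff = _functionals(
                        model, theta, np.stack([Xf, Xbf], axis=1), level, y, order
                    )
                    fc = _functionals(
                        model, theta, np.stack([Xc, Xbc], axis=1), level - 1, y, order
                    )
                for k in keys:
                    if m == settings.m_star:
                        acc_f[k][lo + ids] += ff[k][:, 0]
                        acc_c[k][lo + ids] += fc[k][:, 0]
                    else:
                        acc_f[k][lo + ids] += ff[k][:, 0] - ff[k][:, 1]
                        acc_c[k][lo + ids] += fc[k][:, 0] - fc[k][:, 1]
            done = met_f & met_c & (m >= settings.m_star)
            if np.any(done):
                keep = ~done
                ids = ids[keep]
                Xf, Xbf, Xc, Xbc = Xf[keep], Xbf[keep], Xc[keep], Xbc[keep]
    return acc_f, acc_c, tau_f, tau_c, capped


def _rng(seed, *key):
    """Deterministic child stream keyed by (seed, *key); independent across keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *key]))


# ---------------------------------------------------------------------------
# Public single-replicate operations
# ---------------------------------------------------------------------------


def xi_level0(
    model, theta, obs, settings: EstimatorSettings = EstimatorSettings(), seed=None
) -> IncrementEstimate:
    """Xi^0: the unbiased level-0 smoothed-moment estimator (one chain)."""
    theta = _theta_array(theta)
    y = _obs_array(obs)
    acc, tau, capped = _run_level0(
        model, theta, y, 1, settings, np.random.default_rng(seed)
    )
    return IncrementEstimate(
        level=0,
        xi_score=acc["score"][0],
        xi_outer=acc["outer"][0],
        xi_hess=acc["hess"][0],
        meeting_times=(int(tau[0]),),
        truncated_flag=bool(capped[0]),
    )


def xi_level_l(
    model, theta, obs, level: int,
    settings: EstimatorSettings = EstimatorSettings(), seed=None,
) -> IncrementEstimate:
    """Xi^l = pi_hat^l - pi_hat^{l-1} from one C-CCPF chain (l >= 1)."""
    theta = _theta_array(theta)
    y = _obs_array(obs)
    acc_f, acc_c, tau_f, tau_c, capped = _run_level_l(
        model, theta, y, level, 1, settings, np.random.default_rng(seed)
    )
    return IncrementEstimate(
        level=level,
        xi_score=acc_f["score"][0] - acc_c["score"][0],
        xi_outer=acc_f["outer"][0] - acc_c["outer"][0],
        xi_hess=acc_f["hess"][0] - acc_c["hess"][0],
        meeting_times=(int(tau_f[0]), int(tau_c[0])),
        truncated_flag=bool(capped[0]),
    )


# ---------------------------------------------------------------------------
# Randomized estimators
# ---------------------------------------------------------------------------


def _stack_sums(model, theta, y, level_draws, dist, settings, seed, role, order):
    """Tail-weighted level sums for a batch of replicates with given L draws.

    Returns dict of (M, ...) arrays: sum_{l<=L_k} Xi_k^l / P_bar(l), plus
    meeting-time and cap diagnostics.
    """
    M = level_draws.size
    d_th = model.param_dim
    keys = ["score"] if order == 1 else ["score", "outer", "hess"]
    shapes = {"score": (d_th,), "outer": (d_th, d_th), "hess": (d_th, d_th)}
    sums = {k: np.zeros((M,) + shapes[k]) for k in keys}
    tau_max = 0
    n_capped = 0
    for l in range(int(level_draws.max()) + 1):
        ids = np.flatnonzero(level_draws >= l)
        if ids.size == 0:
            continue
        w = 1.0 / dist.tail(l)
        rng = _rng(seed, role, l)
        if l == 0:
            acc, tau, capped = _run_level0(
                model, theta, y, ids.size, settings, rng, order=order
            )
            for k in keys:
                sums[k][ids] += w * acc[k]
            tau_max = max(tau_max, int(tau.max(initial=0)))
        else:
            acc_f, acc_c, tau_f, tau_c, capped = _run_level_l(
                model, theta, y, l, ids.size, settings, rng, order=order
            )
            for k in keys:
                sums[k][ids] += w * (acc_f[k] - acc_c[k])
            tau_max = max(tau_max, int(tau_f.max(initial=0)), int(tau_c.max(initial=0)))
        n_capped += int(capped.sum())
    return sums, tau_max, n_capped


def unbiased_score(
    model, theta, obs, dist: LevelDistribution,
    settings: EstimatorSettings = EstimatorSettings(),
    M: int = 1, seed=None,
):
    """The randomized-level unbiased score estimator, averaged over M replicates.

    Each replicate draws its own level L ~ P_L, computes Xi^0 and independent
    Xi^l for l <= L, and returns ``sum_l Xi^l / P_bar_L(l)``.
    Returns (score_estimate, diagnostics).
    """
    theta = _theta_array(theta)
    y = _obs_array(obs)
    rng = _rng(seed, 0)
    draws = dist.sample(rng, size=M).astype(np.int64)
    sums, tau_max, n_capped = _stack_sums(
        model, theta, y, draws, dist, settings, seed, role=1, order=1
    )
    diag = {
        "levels": draws,
        "meeting_time_max": tau_max,
        "capped_fraction": n_capped / max(1, M),
        "per_replicate": sums["score"],
    }
    return sums["score"].mean(axis=0), diag


def unbiased_hessian(
    model, theta, obs, dist: LevelDistribution, M: int = 1,
    settings: EstimatorSettings = EstimatorSettings(), seed=None,
) -> HessianEstimate:
    """The unbiased estimator of the observed information (negative Hessian).

    Per replicate k: levels (L_k, L~_k) are drawn independently from P_L; one
    chain stack supplies the tail-weighted sums of Xi(G^(i)), Xi(G^(i)G^(j))
    and Xi(H^(ij)) up to L_k, an independent stack supplies the score sums up
    to L~_k, and the replicate estimate is
    ``S_i S~_j - sum Xi(G G)_ij / P_bar - sum Xi(H)_ij / P_bar`` for i <= j,
    mirrored to a symmetric matrix.  The aggregate is the replicate mean.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    theta = _theta_array(theta)
    y = _obs_array(obs)
    rng = _rng(seed, 0)
    L = dist.sample(rng, size=M).astype(np.int64)
    L_til = dist.sample(rng, size=M).astype(np.int64)
    sums1, tau1, cap1 = _stack_sums(
        model, theta, y, L, dist, settings, seed, role=1, order=2
    )
    sums2, tau2, cap2 = _stack_sums(
        model, theta, y, L_til, dist, settings, seed, role=2, order=1
    )
    prod = sums1["score"][:, :, None] * sums2["score"][:, None, :]
    raw = prod - sums1["outer"] - sums1["hess"]

    def _mirror(mat):
        iu = np.triu_indices(model.param_dim)
        out = np.zeros_like(mat)
        out[..., iu[0], iu[1]] = mat[..., iu[0], iu[1]]
        out[..., iu[1], iu[0]] = mat[..., iu[0], iu[1]]
        return out

    per = _mirror(raw)  # only (i, j) with i <= j estimated, then reflected
    s1 = sums1["score"].mean(axis=0)
    s2 = sums2["score"].mean(axis=0)
    pom = _mirror(
        s1[:, None] * s2[None, :] - sums1["outer"].mean(0) - sums1["hess"].mean(0)
    )
    return HessianEstimate(
        per_replicate=per,
        aggregate=per.mean(axis=0),
        levels=L,
        levels_tilde=L_til,
        meeting_time_max=max(tau1, tau2),
        capped_fraction=(cap1 + cap2) / max(1, 2 * M),
        aggregate_product_of_means=pom,
    )


def xi_functional_increments(
    model, theta, obs, level: int, R: int,
    settings: EstimatorSettings = EstimatorSettings(), seed=None, order: int = 2,
):
    """R independent draws of Xi^l for each tracked path functional.

    Returns (dict with ``score`` (R, d), ``outer`` and ``hess``
    (R, d, d) increment arrays, diagnostics).  At level 0 the increments are
    the pi_hat^0 moments themselves.  The summed entrywise sample variance
    of the ``hess`` increments over R is the level-variance diagnostic.
    """
    theta = _theta_array(theta)
    y = _obs_array(obs)
    if level == 0:
        acc, tau, capped = _run_level0(
            model, theta, y, R, settings, _rng(seed, 1, 0), order=order
        )
        inc = dict(acc)
        taus = (tau,)
    else:
        acc_f, acc_c, tau_f, tau_c, capped = _run_level_l(
            model, theta, y, level, R, settings, _rng(seed, 1, level), order=order
        )
        inc = {k: acc_f[k] - acc_c[k] for k in acc_f}
        taus = (tau_f, tau_c)
    diag = {"meeting_times": taus, "capped_fraction": float(capped.mean())}
    return inc, diag


def _plugin_hessian(acc):
    """Plug-in observed-information assembly of one stack's pi_hat moments."""
    p = acc["score"]
    return p[:, :, None] * p[:, None, :] - acc["outer"] - acc["hess"]


def hessian_increment_sample(
    model, theta, obs, level: int, R: int,
    settings: EstimatorSettings = EstimatorSettings(), seed=None,
):
    """R independent draws of the level-l Hessian increment matrix.

    The increment of the plug-in fixed-level Hessian estimate between levels
    l and l-1, computed from a single coupled chain per replicate:

        inc^l = [p^l p^l* - pi_hat^l(G G*) - pi_hat^l(H)]
              - [p^{l-1} p^{l-1}* - pi_hat^{l-1}(G G*) - pi_hat^{l-1}(H)],

    with p^s = pi_hat^s(score) and both levels read off the same C-CCPF run
    (l = 0 returns the level-0 term alone).  Because every moment of the two
    levels shares one chain, the product and outer terms largely cancel --
    exactly so when the chains coalesce at the burn-in sweep -- and the
    increment inherits the strong-coupling rate: its variance is the
    quantity whose decay in Delta_l the level-variance experiments measure.
    Returns (increments (R, d_theta, d_theta), diagnostics).
    """
    theta = _theta_array(theta)
    y = _obs_array(obs)
    if level == 0:
        acc, tau, capped = _run_level0(
            model, theta, y, R, settings, _rng(seed, 1, 0), order=2
        )
        inc = _plugin_hessian(acc)
        taus = (tau,)
    else:
        acc_f, acc_c, tau_f, tau_c, capped = _run_level_l(
            model, theta, y, level, R, settings, _rng(seed, 1, level), order=2
        )
        inc = _plugin_hessian(acc_f) - _plugin_hessian(acc_c)
        taus = (tau_f, tau_c)
    inc = 0.5 * (inc + inc.swapaxes(-1, -2))
    diag = {"meeting_times": taus, "capped_fraction": float(capped.mean())}
    return inc, diag
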