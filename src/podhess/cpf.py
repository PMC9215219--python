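"""Conditional particle filter (CPF) kernels and their couplings.

The CPF is a Markov kernel on trajectory space that leaves the discretized
smoothing distribution pi_theta^l invariant: a bootstrap particle filter in
which one particle slot is frozen to a reference trajectory (weighted like
any other particle, never resampled away), and whose output is a single
trajectory drawn by ancestral tracing from the final weights.

The coupled CPF (CCPF) runs two such systems with common proposal noise and
coupled resampling indices; once the two output trajectories are equal they
remain equal forever (coalescence is absorbing), which is what turns finite
chain runs into unbiased estimates of smoothed expectations.

Implementation note: all kernels are thin wrappers around one batched sweep
(:func:`_sweep`) that advances S coupled particle systems for R independent
replicates simultaneously, with the particle, system and replicate axes
vectorized.  S is 1 (plain CPF), 2 (CCPF, or the two-level CPF used at
initialization) or 4 (the two-level coupled CCPF).  Systems at the same
discretization level consume one shared Brownian increment stream per
particle slot; systems one level coarser consume sums of consecutive pairs
of the same increments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .euler import LatticePath
from .models import DiffusionModel, _theta_array

__all__ = [
    "ParticleSystem",
    "CoupledPairState",
    "WeightDegeneracyError",
    "maximal_coupling_indices",
    "inversion_coupling_indices",
    "cpf_kernel",
    "driving_ccpf",
    "ccpf_kernel",
    "init_pair",
    "DEFAULT_N_PARTICLES",
]

DEFAULT_N_PARTICLES = 32


class WeightDegeneracyError(RuntimeError):
    """All particle weights vanished at some observation time."""


@dataclass(frozen=True)
class ParticleSystem:
    """Snapshot of one particle system after a sweep (diagnostic object)."""

    level: int
    trajectories: np.ndarray  # (N, n_grid, d) ancestrally traced paths
    ancestors: np.ndarray  # (n, N) resampling index history
    log_weights: np.ndarray  # (N,) final-time log weights


@dataclass(frozen=True)
class CoupledPairState:
    """A pair of same-level trajectories evolved by the CCPF kernel."""

    first: LatticePath
    second: LatticePath

    def __post_init__(self):
        if self.first.level != self.second.level:
            raise ValueError("paired trajectories must share a level")

    @property
    def coalesced(self) -> bool:
        return np.array_equal(self.first.values, self.second.values)


# ---------------------------------------------------------------------------
# Index couplings
# ---------------------------------------------------------------------------


def _check_pmf(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("probability vectors must be non-negative")
    if not math.isclose(r.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("probability vectors must sum to one")
    return r


def maximal_coupling_indices(r, r_bar, seed=None):
    """Sample (i, j) with i ~ r, j ~ r_bar and P(i = j) = sum_m min(r_m, r_bar_m).

    Standard gamma-coupling construction: draw i ~ r; accept j = i with
    probability min(r_i, r_bar_i)/r_i, otherwise draw j from the normalized
    residual (r_bar - min(r, r_bar))+.
    """
    r = _check_pmf(r)
    r_bar = _check_pmf(r_bar)
    rng = np.random.default_rng(seed)
    i = int(rng.choice(r.size, p=r))
    overlap = np.minimum(r, r_bar)
    accept = overlap[i] / r[i] if r[i] > 0 else 0.0
    if rng.random() < accept:
        return i, i
    residual = r_bar - overlap
    z = residual.sum()
    if z <= 0.0:  # full overlap; cannot reach here unless accept < 1 numerically
        return i, i
    j = int(rng.choice(r_bar.size, p=residual / z))
    return i, j


def inversion_coupling_indices(r, r_bar, common_uniform: float):
    """Couple two pmfs by inverting both CDFs at the same uniform."""
    r = _check_pmf(r)
    r_bar = _check_pmf(r_bar)
    u = float(common_uniform)
    i = int(np.searchsorted(np.cumsum(r), u, side="right"))
    j = int(np.searchsorted(np.cumsum(r_bar), u, side="right"))
    return min(i, r.size - 1), min(j, r_bar.size - 1)


def _invert_rows(pmf: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Row-wise CDF inversion of unnormalized pmfs.  pmf: (R, N); u: (R, K).

    Each row is normalized by its own sum (an all-zero row maps every draw
    to the last index; callers guard that case).  Implemented by
    searchsorted on the row-offset concatenated CDF, which is
    O((RN + RK) log(RN)) instead of the O(RKN) broadcast; normalizing by
    the actual row sum keeps every row's CDF in [0, 1], which the global
    sortedness of the offset trick relies on.
    """
    R, N = pmf.shape
    cdf = np.cumsum(pmf, axis=-1)
    cdf = cdf / np.maximum(cdf[:, -1:], 1e-300)
    offs = 2.0 * np.arange(R)[:, None]
    pos = np.searchsorted(
        (cdf + offs).ravel(), (np.minimum(u, 1.0 - 1e-16) + offs).ravel(), side="right"
    ).reshape(R, -1)
    idx = pos - np.arange(R)[:, None] * N
    return np.minimum(np.maximum(idx, 0), N - 1)


def _inversion_indices_batch(w: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized CDF inversion.  w: (R, S, N) pmfs; u: (R, K) shared uniforms.

    Returns (R, S, K) indices; the same uniform is used by all S systems of a
    replicate, which is the coupling used in the simulations.
    """
    R, S, N = w.shape
    return np.stack([_invert_rows(w[:, s], u) for s in range(S)], axis=1)


def _sorted_invert(pmf: np.ndarray, order: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Invert a pmf's CDF taken in the given particle order.

    pmf, order: (R, N); u: (R, K).  Two pmfs inverted at the same uniform
    in value-sorted order either agree or pick value-adjacent particles,
    so a mismatch between two such draws is cheap when particle positions
    are close -- the positional coupling used across discretization levels.
    """
    ranks = _invert_rows(np.take_along_axis(pmf, order, axis=1), u)
    return np.take_along_axis(order, ranks, axis=1)


def _maximal_indices_batch(
    w: np.ndarray, K: int, rng, orders: Optional[np.ndarray] = None,
    two_level_pair: bool = False,
) -> np.ndarray:
    """Coupled categorical draws for S systems, K draws per replicate.

    w: (R, S, N) with S in {1, 2, 4}; ``orders`` (R, S, N) are per-system
    value-sort permutations of the particle slots (used by the positional
    level links; optional).

    S = 2 with ``two_level_pair=False``: exact maximal coupling of the two
    pmfs (gamma construction).  With ``two_level_pair=True`` (one fine and
    one coarse system) the pair is positionally coupled instead: both CDFs
    are inverted at one shared uniform in value-sorted order, so the draws
    agree whenever the sorted CDFs align and otherwise pick value-adjacent
    particles.

    S = 4 (systems ordered fine, fine-bar, coarse, coarse-bar): with
    probability ``A = sum_i min_s w_s(i)`` all four indices are drawn equal
    from the normalized four-way overlap; otherwise the fine and coarse
    x-chain draws are positionally coupled through one shared uniform
    (value-sorted inversion), and each chain pair is completed by an exact
    gamma-partner link (0 -> 1 and 2 -> 3) reusing one uniform stream.
    Consequences: equal weight vectors within either chain pair force
    equal draws for that pair (per-level absorbing coalescence in both
    directions); both chain-pair meeting probabilities equal the full
    pairwise overlaps; and a fine/coarse mismatch within a chain costs a
    value-adjacent particle rather than an arbitrary one, which is what
    keeps the level increments small.  Each index is marginally
    distributed by its own pmf.  Returns (R, S, K) indices.
    """
    R, S, N = w.shape
    tiny = 1e-300
    if S == 1:
        u = rng.random((R, K))
        return _inversion_indices_batch(w, u)

    _invert = _invert_rows
    if orders is None:
        orders = np.broadcast_to(np.arange(N), (R, S, N))

    if S == 2 and two_level_pair:
        u1 = rng.random((R, K))
        i = _sorted_invert(w[:, 0], orders[:, 0], u1)
        j = _sorted_invert(w[:, 1], orders[:, 1], u1)
        return np.stack([i, j], axis=1)

    if S == 2:
        # exact maximal coupling of the two pmfs (gamma construction)
        u1, u2, u3 = (rng.random((R, K)) for _ in range(3))
        p, q = w[:, 0], w[:, 1]
        i = _invert(p, u1)
        overlap = np.minimum(p, q)
        accept = np.take_along_axis(overlap, i, 1) / np.maximum(
            np.take_along_axis(p, i, 1), tiny
        )
        rem = q - overlap
        z = rem.sum(-1)
        j = np.where(
            (u2 < accept) | (z <= tiny)[:, None], i, _invert(rem, u3)
        )
        return np.stack([i, j], axis=1)

    # S == 4, systems ordered (fine, fine-bar, coarse, coarse-bar).
    # Common overlap branch; on the residuals, a nested gamma construction:
    # the fine pair (0,1) is coupled exactly maximally, then each chain's
    # coarse index accept/rejects off its own fine index with the SAME
    # uniforms in both chains.  The fine-chain pair and both within-chain
    # level pairs are then all exactly pairwise-maximally coupled, and the
    # coarse-chain pair inherits near-maximal matching through the shared
    # uniforms once the chains are close.
    alpha = w.min(axis=1)  # (R, N) overlap of all four
    A = alpha.sum(-1)
    u0, u1, u2, u5, u6 = (rng.random((R, K)) for _ in range(5))
    take_common = u0 < A[:, None]
    i_com = _invert(alpha, u1)
    res = w - alpha[:, None, :]  # (R, S, N); each residual sums to 1 - A

    def _accept_prob(ra, rb, i):
        ov = np.minimum(ra, rb)
        return np.take_along_axis(ov, i, 1) / np.maximum(
            np.take_along_axis(ra, i, 1), tiny
        )

    def _gamma_partner(ra, rb, i, u_acc, u_draw):
        # maximal coupling partner: given i ~ ra/mass(ra), return
        # j ~ rb/mass(rb) with the largest possible P(j = i); works on the
        # normalized pmfs so unequal masses are handled correctly
        pa = ra / np.maximum(ra.sum(-1), tiny)[:, None]
        pb = rb / np.maximum(rb.sum(-1), tiny)[:, None]
        rem = pb - np.minimum(pa, pb)
        z = rem.sum(-1)
        j = _invert(rem, u_draw)
        return np.where(
            (u_acc < _accept_prob(pa, pb, i)) | (z <= tiny)[:, None], i, j
        )

    # x-chain level link: positional coupling (one uniform, value-sorted
    # inversion) so a fine/coarse mismatch picks a value-adjacent particle;
    # chain pairs: exact gamma partners, reusing one uniform stream so that
    # with equal level weights the bar draws mirror the x draws exactly
    i0 = _sorted_invert(res[:, 0], orders[:, 0], u2)
    i2 = _sorted_invert(res[:, 2], orders[:, 2], u2)
    i1 = _gamma_partner(res[:, 0], res[:, 1], i0, u5, u6)  # fine pair maximal
    i3 = _gamma_partner(res[:, 2], res[:, 3], i2, u5, u6)  # coarse pair maximal
    out = np.empty((R, S, K), dtype=np.int64)
    for s, i_s in enumerate((i0, i1, i2, i3)):
        out[:, s] = np.where(take_common, i_com, i_s)
    return out


# ---------------------------------------------------------------------------
# The batched sweep
# ---------------------------------------------------------------------------


def _normalized_weights(lw: np.ndarray, k: int) -> np.ndarray:
    """Log-weight normalization with max-subtraction.  lw: (R, S, N)."""
    m = lw.max(axis=-1, keepdims=True)
    if not np.all(np.isfinite(m)):
        bad = np.argwhere(~np.isfinite(m))
        raise WeightDegeneracyError(
            f"all particle weights vanished at unit time {k} (replicate/system {bad[0][:2]})"
        )
    w = np.exp(lw - m)
    return w / w.sum(axis=-1, keepdims=True)


def _girsanov_cell(model, theta, x, dxv, dt, acc_s, acc_h):
    """Add one Euler cell's Girsanov derivative terms to the accumulators.

    x: left endpoints (..., d); dxv: increments (..., d).  acc_s (..., d_th)
    always updated; acc_h (..., d_th, d_th) only when provided.
    """
    acc_s += -0.5 * dt * model.bsq_d1(theta, x)
    acc_s += np.einsum("...id,...d->...i", model.psi_d1(theta, x), dxv)
    if acc_h is not None:
        acc_h += -0.5 * dt * model.bsq_d2(theta, x)
        if not model.psi_d2_zero:
            acc_h += np.einsum("...ijd,...d->...ij", model.psi_d2(theta, x), dxv)


def _sweep(
    model: DiffusionModel,
    theta: np.ndarray,
    y: np.ndarray,
    refs: Sequence[np.ndarray],
    levels: Sequence[int],
    N: int,
    rng,
    coupling: str = "maximal",
    return_systems: bool = False,
    track_order: int = 0,
):
    """One conditional-particle-filter sweep for S coupled systems.

    refs[s]: (R, G_s, d) frozen reference trajectories at levels[s].  All
    systems at the common fine level share one increment stream; coarse
    systems use pairwise sums.

    With ``track_order`` 1 or 2, each particle carries its accumulated
    score (and Hessian) path-functional values through propagation and
    resampling, and the sweep additionally returns the weighted averages
    over the final particle cloud -- the Rao-Blackwellized smoothing
    estimates of the functionals, which have the same expectation as
    evaluating the functionals on the single returned trajectory but much
    smaller variance.

    Returns (output trajectories [(R, G_s, d)], final log-weights, system
    snapshots or None, RB-estimate dict or None).
    """
    S = len(refs)
    R = refs[0].shape[0]
    d = model.state_dim
    d_th = model.param_dim
    n = y.shape[0]
    fine = max(levels)
    if min(levels) < fine - 1:
        raise ValueError("systems may span at most two adjacent levels")
    spu = [2**lv for lv in levels]
    spu_f = 2**fine
    dt = [2.0 ** (-lv) for lv in levels]
    dt_f = 2.0 ** (-fine)
    sq_f = math.sqrt(dt_f)
    diag = model.diffusion_diag
    x0 = np.broadcast_to(model.initial_state, (R, S, N, d))

    cur = x0.copy()
    segs = [np.empty((n, R, N, spu[s], d)) for s in range(S)]
    anc = np.empty((n, R, S, N), dtype=np.int64)
    free = N - 1  # slot N-1 holds the frozen reference

    fine_ix = [s for s in range(S) if levels[s] == fine]
    coarse_ix = [s for s in range(S) if levels[s] == fine - 1]
    # an S = 2 system spanning two levels is the two-level CPF: its pair
    # coupling is positional (cross-level), not a chain coupling
    two_level_pair = S == 2 and len(coarse_ix) == 1

    track = track_order > 0
    acc_s = np.zeros((R, S, N, d_th)) if track else None
    acc_h = np.zeros((R, S, N, d_th, d_th)) if track_order == 2 else None

    final_lw = None
    final_idx = None
    final_w = None
    for k in range(1, n + 1):
        if track:
            frozen_s = acc_s[:, :, free].copy()
            frozen_h = acc_h[:, :, free].copy() if acc_h is not None else None
        dW = rng.standard_normal((spu_f, R, N, d)) * sq_f
        # propagate fine systems with the shared stream
        for s in fine_ix:
            x = cur[:, s]
            for t in range(spu_f):
                a = model.drift(theta, x)
                if diag is not None:
                    dxv = a * dt_f + diag * dW[t]
                else:
                    dxv = a * dt_f + np.einsum(
                        "ij,...j->...i", model.sigma_matrix(x), dW[t]
                    )
                if track:
                    _girsanov_cell(
                        model, theta, x, dxv, dt_f, acc_s[:, s],
                        acc_h[:, s] if acc_h is not None else None,
                    )
                x = x + dxv
                segs[s][k - 1, :, :, t] = x
            cur[:, s] = x
        if coarse_ix:
            dWc = dW[0::2] + dW[1::2]
            dt_c = 2.0 * dt_f
            for s in coarse_ix:
                x = cur[:, s]
                for t in range(spu_f // 2):
                    a = model.drift(theta, x)
                    if diag is not None:
                        dxv = a * dt_c + diag * dWc[t]
                    else:
                        dxv = a * dt_c + np.einsum(
                            "ij,...j->...i", model.sigma_matrix(x), dWc[t]
                        )
                    if track:
                        _girsanov_cell(
                            model, theta, x, dxv, dt_c, acc_s[:, s],
                            acc_h[:, s] if acc_h is not None else None,
                        )
                    x = x + dxv
                    segs[s][k - 1, :, :, t] = x
                cur[:, s] = x
        # frozen reference occupies slot N-1
        for s in range(S):
            lo, hi = (k - 1) * spu[s] + 1, k * spu[s] + 1
            segs[s][k - 1, :, free] = refs[s][:, lo:hi]
            cur[:, s, free] = refs[s][:, hi - 1]
        if track:
            # the frozen slot's accumulation follows its reference segment,
            # not the free propagation it was overwritten from
            for s in range(S):
                lo, hi = (k - 1) * spu[s], k * spu[s]
                Xl = refs[s][:, lo:hi]  # (R, spu_s, d) left endpoints
                dXs = refs[s][:, lo + 1 : hi + 1] - Xl
                cs = -0.5 * dt[s] * model.bsq_d1(theta, Xl).sum(axis=-2)
                cs += np.einsum("...kid,...kd->...i", model.psi_d1(theta, Xl), dXs)
                acc_s[:, s, free] = frozen_s[:, s] + cs
                if acc_h is not None:
                    ch = -0.5 * dt[s] * model.bsq_d2(theta, Xl).sum(axis=-3)
                    if not model.psi_d2_zero:
                        ch += np.einsum(
                            "...kijd,...kd->...ij", model.psi_d2(theta, Xl), dXs
                        )
                    acc_h[:, s, free] = frozen_h[:, s] + ch
        if not np.all(np.isfinite(cur)):
            raise WeightDegeneracyError(f"non-finite particle state at unit time {k}")

        xo = cur[..., : model.obs_dim]
        lw = model.obs_logdensity(theta, xo, y[k - 1], 0)  # (R, S, N)
        w = _normalized_weights(lw, k)
        if track:
            acc_s += model.obs_logdensity(theta, xo, y[k - 1], 1)
            if acc_h is not None:
                acc_h += model.obs_logdensity(theta, xo, y[k - 1], 2)

        if k < n:
            if coupling == "inversion" or S == 1:
                u = rng.random((R, free))
                idx = _inversion_indices_batch(w, u)  # (R, S, free)
            elif coupling == "maximal":
                orders = np.argsort(cur[..., 0], axis=-1)
                idx = _maximal_indices_batch(
                    w, free, rng, orders=orders, two_level_pair=two_level_pair
                )
            else:
                raise ValueError(f"unknown coupling {coupling!r}")
            anc[k - 1, :, :, :free] = idx
            anc[k - 1, :, :, free] = free
            gather = np.concatenate(
                [idx, np.full((R, S, 1), free, dtype=np.int64)], axis=-1
            )
            cur = np.take_along_axis(cur, gather[..., None], axis=2)
            if track:
                acc_s = np.take_along_axis(acc_s, gather[..., None], axis=2)
                if acc_h is not None:
                    acc_h = np.take_along_axis(acc_h, gather[..., None, None], axis=2)
        else:
            anc[k - 1] = np.arange(N)[None, None, :]  # no resampling at n
            if coupling == "inversion" or S == 1:
                u = rng.random((R, 1))
                final_idx = _inversion_indices_batch(w, u)[..., 0]  # (R, S)
            else:
                orders = np.argsort(cur[..., 0], axis=-1)
                final_idx = _maximal_indices_batch(
                    w, 1, rng, orders=orders, two_level_pair=two_level_pair
                )[..., 0]
            final_lw = lw
            final_w = w

    # ancestral tracing of the selected trajectories
    outs = []
    r_ix = np.arange(R)[:, None]
    s_all = np.arange(S)[None, :]
    for s in range(S):
        out = np.empty((R, n * spu[s] + 1, d))
        out[:, 0] = model.initial_state
        outs.append(out)
    # idx holds the label carried while propagating over (k-1, k]; stepping to
    # the previous segment goes through the resampling at time k-1
    idx = final_idx.copy()  # (R, S)
    for k in range(n, 0, -1):
        for s in range(S):
            lo, hi = (k - 1) * spu[s] + 1, k * spu[s] + 1
            outs[s][:, lo:hi] = segs[s][k - 1][r_ix[:, 0], idx[:, s]]
        if k >= 2:
            idx = anc[k - 2][r_ix, s_all, idx]

    systems = None
    if return_systems:
        systems = []
        for s in range(S):
            trajs = np.empty((N, n * spu[s] + 1, d))
            trajs[:, 0] = model.initial_state
            jdx = np.arange(N)
            for k in range(n, 0, -1):
                lo, hi = (k - 1) * spu[s] + 1, k * spu[s] + 1
                trajs[:, lo:hi] = segs[s][k - 1, 0, jdx]
                if k >= 2:
                    jdx = anc[k - 2, 0, s, jdx]
            systems.append(
                ParticleSystem(
                    level=levels[s],
                    trajectories=trajs,
                    ancestors=anc[:, 0, s].copy(),
                    log_weights=final_lw[0, s].copy(),
                )
            )

    rb = None
    if track:
        rb = {"score": np.einsum("rsn,rsni->rsi", final_w, acc_s)}
        if track_order == 2:
            rb["outer"] = np.einsum("rsn,rsni,rsnj->rsij", final_w, acc_s, acc_s)
            rb["hess"] = np.einsum("rsn,rsnij->rsij", final_w, acc_h)
    return outs, final_lw, systems, rb


# ---------------------------------------------------------------------------
# Spec-level kernels (single chain; R = 1 through the batched sweep)
# ---------------------------------------------------------------------------


def _obs_array(obs) -> np.ndarray:
    return obs.values if hasattr(obs, "values") else np.atleast_2d(np.asarray(obs, float))


def cpf_kernel(
    model, theta, obs, reference: LatticePath, N: int = DEFAULT_N_PARTICLES,
    level: Optional[int] = None, seed=None,
) -> LatticePath:
    """One conditional-particle-filter move from the reference trajectory."""
    theta = _theta_array(theta)
    y = _obs_array(obs)
    level = reference.level if level is None else level
    if N == 1:
        return reference
    if N < 1:
        raise ValueError("need at least one particle")
    rng = np.random.default_rng(seed)
    outs, _, _, _ = _sweep(
        model, theta, y, [reference.values[None]], [level], N, rng
    )
    return LatticePath(level, outs[0][0])


def driving_ccpf(
    model, theta, obs, frozen_pair: CoupledPairState, N: int = DEFAULT_N_PARTICLES,
    level: Optional[int] = None, seed=None, coupling: str = "maximal",
):
    """The coupled particle filter with a frozen trajectory pair.

    Returns both particle systems and the ancestrally traced output pair
    drawn with coupled final-weight indices.
    """
    theta = _theta_array(theta)
    y = _obs_array(obs)
    level = frozen_pair.first.level if level is None else level
    if N < 2:
        raise ValueError("the driving CCPF needs at least two particles")
    rng = np.random.default_rng(seed)
    outs, _, systems, _ = _sweep(
        model,
        theta,
        y,
        [frozen_pair.first.values[None], frozen_pair.second.values[None]],
        [level, level],
        N,
        rng,
        coupling=coupling,
        return_systems=True,
    )
    pair = (LatticePath(level, outs[0][0]), LatticePath(level, outs[1][0]))
    return systems[0], systems[1], pair


def ccpf_kernel(
    model, theta, obs, z: CoupledPairState, N: int = DEFAULT_N_PARTICLES,
    seed=None, coupling: str = "maximal",
) -> CoupledPairState:
    """One step of the CCPF Markov kernel K_0 (or its level-l analogue).

    Marginally each output trajectory is a CPF move from its input; equal
    inputs produce equal outputs (coalescence is absorbing).
    """
    _, _, pair = driving_ccpf(model, theta, obs, z, N=N, seed=seed, coupling=coupling)
    return CoupledPairState(pair[0], pair[1])


def init_pair(
    model, theta, obs, N: int = DEFAULT_N_PARTICLES, level: int = 0, seed=None,
    coupling: str = "maximal",
) -> CoupledPairState:
    """Draw from the initial distribution of the CCPF chain.

    Two independent Euler prior paths from x_star; the first coordinate gets
    one CPF move (so it is one kernel application ahead of the second, which
    stays frozen at its prior draw).
    """
    from .euler import simulate_prior_path

    theta = _theta_array(theta)
    y = _obs_array(obs)
    rng = np.random.default_rng(seed)
    xp = simulate_prior_path(model, theta, y.shape[0], level, rng)
    xbp = simulate_prior_path(model, theta, y.shape[0], level, rng)
    first = cpf_kernel(
        model, theta, obs, LatticePath(level, xp), N=N, level=level,
        seed=rng.integers(2**31),
    )
    return CoupledPairState(first, LatticePath(level, xbp))
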