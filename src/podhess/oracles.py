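"""Ground-truth machinery for linear-Gaussian and tiny nonlinear models.

Three independent routes to smoothed/likelihood quantities:

* exact Kalman filtering of the *level-l Euler-discretized* linear SDE (the
  recursion runs on the fine grid with measurement updates at unit times, so
  it matches the discretized smoothing distribution pi_theta^l exactly, not
  the continuous-time model);
* central finite differences of any log-likelihood in theta, giving the score
  and the observed information (negative Hessian);
* brute-force tensor-grid quadrature of the discretized smoothing density for
  univariate models with very few latent grid points.

These are oracles for testing the particle estimators, never used inside
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .functionals import SmoothedMoments, evaluate_path_functionals
from .models import DiffusionModel, _theta_array

__all__ = [
    "LinearGaussianSystem",
    "discretized_linear_system",
    "exact_ou_unit_system",
    "kalman_loglik",
    "fd_score_hessian",
    "quadrature_smoother",
]


@dataclass(frozen=True)
class LinearGaussianSystem:
    """x_{k+1} = M x_k + m + N(0, C) per fine step; y = x + N(0, R) at unit times."""

    M: np.ndarray  # (d, d)
    m: np.ndarray  # (d,)
    C: np.ndarray  # (d, d) process noise per step
    R: np.ndarray  # (d_y, d_y) observation noise
    x0: np.ndarray  # (d,)
    steps_per_unit: int

    def __post_init__(self):
        for name in ("M", "m", "C", "R", "x0"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        w = np.linalg.eigvalsh(self.R)
        if np.any(w <= 0):
            raise ValueError("observation covariance must be positive definite")


def discretized_linear_system(
    model: DiffusionModel, theta, level: int
) -> LinearGaussianSystem:
    """Level-l Euler discretization of a linear-drift model as a linear-Gaussian system."""
    if model.linear_coeffs is None:
        raise ValueError(f"model {model.name!r} has no linear drift representation")
    theta = _theta_array(theta)
    F, c = model.linear_coeffs(theta)
    d = model.state_dim
    dt = 2.0 ** (-level)
    sig = model.sigma_matrix(model.initial_state)
    v = theta[-1]
    return LinearGaussianSystem(
        M=np.eye(d) + dt * F,
        m=dt * c,
        C=dt * (sig @ sig.T),
        R=v * np.eye(model.obs_dim),
        x0=model.initial_state,
        steps_per_unit=2**level,
    )


def exact_ou_unit_system(model: DiffusionModel, theta) -> LinearGaussianSystem:
    """Exact unit-time transition for OU models with diagonal linear drift.

    Componentwise, dx = (c - kappa x) dt + s dW has unit-time mean map
    ``x -> e^-kappa x + (c/kappa)(1 - e^-kappa)`` and variance
    ``s^2 (1 - e^-2 kappa) / (2 kappa)``.
    """
    theta = _theta_array(theta)
    F, c = model.linear_coeffs(theta)
    kappa = -np.diag(F)
    if not np.allclose(F, np.diag(np.diag(F))):
        raise ValueError("exact transitions implemented for diagonal drift only")
    s = np.asarray(model.diffusion_diag, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        decay = np.exp(-kappa)
        mean_off = np.where(kappa != 0.0, c / np.where(kappa != 0, kappa, 1.0), c) * (
            1.0 - decay
        )
        mean_off = np.where(kappa != 0.0, mean_off, c)
        var = np.where(
            kappa != 0.0,
            s**2 * (1.0 - np.exp(-2 * kappa)) / np.where(kappa != 0, 2 * kappa, 1.0),
            s**2,
        )
    return LinearGaussianSystem(
        M=np.diag(decay),
        m=mean_off,
        C=np.diag(var),
        R=theta[-1] * np.eye(model.obs_dim),
        x0=model.initial_state,
        steps_per_unit=1,
    )


def kalman_loglik(system: LinearGaussianSystem, obs) -> float:
    """Exact log marginal likelihood by prediction/update recursions.

    Propagates mean and covariance through every fine Euler step and applies
    a measurement update at each unit time (identity observation matrix).
    """
    y = obs.values if hasattr(obs, "values") else np.atleast_2d(np.asarray(obs, float))
    M, m, C = system.M, system.m, system.C
    mu = system.x0.copy()
    P = np.zeros_like(C)
    ll = 0.0
    d_y = y.shape[1]
    for p in range(y.shape[0]):
        for _ in range(system.steps_per_unit):
            mu = M @ mu + m
            P = M @ P @ M.T + C
        S = P[:d_y, :d_y] + system.R
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise np.linalg.LinAlgError("innovation covariance not positive definite")
        innov = y[p] - mu[:d_y]
        sol = np.linalg.solve(S, innov)
        ll += -0.5 * (d_y * np.log(2.0 * np.pi) + logdet + innov @ sol)
        K = np.linalg.solve(S, P[:d_y, :]).T  # (d, d_y) gain
        mu = mu + K @ innov
        P = P - K @ P[:d_y, :]
        P = 0.5 * (P + P.T)
    return float(ll)


def fd_score_hessian(loglik_fn, theta, h: float = 1e-4):
    """Central finite differences of a log-likelihood in theta.

    Returns ``(score, negative_hessian)``; the Hessian is symmetrized by
    averaging with its transpose.  Step per component: h * (1 + |theta_i|).
    """
    theta = np.asarray(theta, dtype=float)
    d = theta.size
    hs = h * (1.0 + np.abs(theta))

    def f(t):
        val = loglik_fn(np.asarray(t, float))
        if not np.isfinite(val):
            raise FloatingPointError("non-finite log-likelihood in finite differences")
        return val

    f0 = f(theta)
    score = np.empty(d)
    hess = np.empty((d, d))
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += hs[i]
        tm[i] -= hs[i]
        fp[i], fm[i] = f(tp), f(tm)
        score[i] = (fp[i] - fm[i]) / (2.0 * hs[i])
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / hs[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            tpp = theta.copy()
            tpp[[i, j]] += [hs[i], hs[j]]
            tpm = theta.copy()
            tpm[[i, j]] += [hs[i], -hs[j]]
            tmp = theta.copy()
            tmp[[i, j]] += [-hs[i], hs[j]]
            tmm = theta.copy()
            tmm[[i, j]] += [-hs[i], -hs[j]]
            hess[i, j] = hess[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (
                4.0 * hs[i] * hs[j]
            )
    hess = 0.5 * (hess + hess.T)
    return score, -hess


# ---------------------------------------------------------------------------
# Dense-grid quadrature smoothing (univariate, a handful of latent points)
# ---------------------------------------------------------------------------


def quadrature_smoother(
    model: DiffusionModel,
    theta,
    obs,
    level: int = 0,
    grid_size: int = 201,
    span: float = 8.0,
    refine_check: bool = False,
) -> SmoothedMoments:
    """Tensor-grid expectation of the path functionals under pi_theta^l.

    Restricted to univariate models with at most three latent lattice points
    (``n * 2**level <= 3``).  The grid for each latent time is centred between
    the deterministic flow and the nearest observation, with a width governed
    by the prior spread; ``refine_check=True`` recomputes on a doubled grid
    and raises if the moments move by more than 1e-5.
    """
    if model.state_dim != 1:
        raise ValueError("quadrature smoothing is univariate only")
    theta = _theta_array(theta)
    y = obs.values if hasattr(obs, "values") else np.atleast_2d(np.asarray(obs, float))
    n = y.shape[0]
    m_lat = n * 2**level
    if m_lat > 3:
        raise ValueError("too many latent grid points for dense quadrature")
    moments = _quadrature_moments(model, theta, y, level, m_lat, grid_size, span)
    if refine_check:
        refined = _quadrature_moments(model, theta, y, level, m_lat, 2 * grid_size, span)
        pairs = [
            (moments.mean_score, refined.mean_score),
            (moments.mean_outer, refined.mean_outer),
            (moments.mean_hess_fun, refined.mean_hess_fun),
        ]
        for a, b in pairs:
            if np.max(np.abs(np.asarray(a) - np.asarray(b))) > 1e-5:
                raise RuntimeError("quadrature grid too coarse; increase grid_size")
    return moments


def _quadrature_moments(model, theta, y, level, m_lat, grid_size, span):
    dt = 2.0 ** (-level)
    spu = 2**level
    x0 = float(model.initial_state[0])
    sig = float(model.sigma_matrix(model.initial_state)[0, 0])
    v = float(theta[-1])

    # deterministic Euler flow as grid centres
    flow = [x0]
    for _ in range(m_lat):
        xk = flow[-1]
        flow.append(xk + float(model.drift(theta, np.array([xk]))[0]) * dt)
    grids = []
    for j in range(1, m_lat + 1):
        sd = np.sqrt(j * dt) * sig
        centre = flow[j]
        half = span * max(sd, np.sqrt(v))
        if j % spu == 0:
            yk = float(y[j // spu - 1, 0])
            centre = 0.5 * (centre + yk)
            half += abs(flow[j] - yk)
        grids.append(np.linspace(centre - half, centre + half, grid_size))

    mesh = np.meshgrid(*grids, indexing="ij")  # m_lat arrays of shape (G,)*m_lat
    # log smoothing density (unnormalized): transitions + observation terms
    logw = np.zeros(mesh[0].shape)
    prev = np.full(mesh[0].shape, x0)
    for j in range(m_lat):
        a = model.drift(theta, prev[..., None])[..., 0]
        mean = prev + a * dt
        logw += -0.5 * np.log(2.0 * np.pi * sig**2 * dt) - (mesh[j] - mean) ** 2 / (
            2.0 * sig**2 * dt
        )
        if (j + 1) % spu == 0:
            yk = float(y[(j + 1) // spu - 1, 0])
            logw += -0.5 * np.log(2.0 * np.pi * v) - (mesh[j] - yk) ** 2 / (2.0 * v)
        prev = mesh[j]
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()

    paths = np.stack([np.full(mesh[0].shape, x0)] + list(mesh), axis=-1)[..., None]
    vals = evaluate_path_functionals(model, theta, paths, y, level=level)
    flat_w = w.reshape(-1)
    d_theta = model.param_dim
    mean_score = flat_w @ vals.score.reshape(-1, d_theta)
    mean_outer = np.einsum(
        "r,rij->ij", flat_w, vals.score_outer.reshape(-1, d_theta, d_theta)
    )
    mean_hess = np.einsum(
        "r,rij->ij", flat_w, vals.hess_fun.reshape(-1, d_theta, d_theta)
    )
    return SmoothedMoments(mean_score, mean_outer, mean_hess)
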