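"""Diffusion + observation model contracts and the built-in SDE models.

A model is a diffusion ``dX_t = a_theta(X_t) dt + sigma(X_t) dW_t`` started at
``x_star``, observed at unit-spaced times ``t_p = p`` through a conditional
density ``g_theta(y_p | x_p)``.  Everything downstream (Euler kernels, Girsanov
path functionals, particle filters) consumes a :class:`DiffusionModel`.

Built-in models are the univariate Ornstein-Uhlenbeck process, a bivariate OU
process and the stochastic FitzHugh-Nagumo neuron model, each with additive
diagonal noise and Gaussian measurement error ``N(x, theta_var * I)`` whose
variance is the last component of the parameter vector.  Their theta-derivative
suppliers (needed by the score/Hessian path functionals) are analytic; user
models without suppliers can be equipped with finite-difference ones via
:func:`with_fd_derivatives`.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DiffusionModel",
    "ParameterVector",
    "ObservationSeries",
    "DegeneracyError",
    "PropagationError",
    "eval_b",
    "b_squared",
    "girsanov_psi",
    "obs_logdensity_derivs",
    "simulate_observations",
    "univariate_ou",
    "bivariate_ou",
    "fitzhugh_nagumo",
    "with_fd_derivatives",
    "get_model",
    "MODELS",
]


class DegeneracyError(RuntimeError):
    """Raised when Sigma(x) = sigma(x) sigma(x)* is numerically singular."""


class PropagationError(RuntimeError):
    """Raised when a simulated state stops being finite."""


@dataclass(frozen=True)
class ParameterVector:
    """A parameter point with per-component positivity constraints.

    ``positivity_mask[i]`` is True for components that must stay strictly
    positive (e.g. an observation variance).  Optimizers project onto the
    constraint; the model formulas use the raw values.
    """

    values: np.ndarray
    positivity_mask: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "positivity_mask", np.asarray(self.positivity_mask, dtype=bool)
        )
        if self.values.shape != self.positivity_mask.shape:
            raise ValueError("values and positivity_mask must have equal shape")
        if np.any(self.values[self.positivity_mask] <= 0.0):
            raise ValueError("masked parameter components must be strictly positive")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def _theta_array(theta) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        return theta.values
    return np.asarray(theta, dtype=float)


@dataclass(frozen=True)
class ObservationSeries:
    """Observations ``y_1, ..., y_n`` at implicit unit-spaced times (T = n)."""

    values: np.ndarray  # (n, d_y)

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[0] < 1:
            raise ValueError("need at least one observation")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def obs_dim(self) -> int:
        return self.values.shape[1]

    # -- CSV / JSON round-trip -------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values, columns=[f"y{i + 1}" for i in range(self.obs_dim)]
        )
        df.insert(0, "time", np.arange(1, self.n + 1))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationSeries":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != "time"]
        return cls(df[cols].to_numpy(dtype=float))

    def to_json(self, path) -> None:
        payload = {"n": int(self.n), "values": self.values.tolist()}
        if hasattr(path, "write"):
            json.dump(payload, path)
        else:
            with open(path, "w") as fh:
                json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ObservationSeries":
        if hasattr(path, "read"):
            payload = json.load(path)
        else:
            with open(path) as fh:
                payload = json.load(fh)
        return cls(np.asarray(payload["values"], dtype=float))


# ---------------------------------------------------------------------------
# Model contract
# ---------------------------------------------------------------------------

# Derivative supplier signatures (all vectorized over leading axes of x):
#   bsq_d1(theta, x)  -> (..., d_theta)            d/dtheta_i ||b_theta(x)||^2
#   bsq_d2(theta, x)  -> (..., d_theta, d_theta)
#   psi_d1(theta, x)  -> (..., d_theta, d)         d/dtheta_i psi,
#                                                  psi = b* Sigma^{-1} sigma*
#   psi_d2(theta, x)  -> (..., d_theta, d_theta, d)
#   obs_logdensity(theta, x, y, order) -> (...,) | (..., dth) | (..., dth, dth)


@dataclass(frozen=True)
class DiffusionModel:
    name: str
    state_dim: int
    param_dim: int
    obs_dim: int
    initial_state: np.ndarray
    positivity_mask: np.ndarray
    drift: Callable[[np.ndarray, np.ndarray], np.ndarray]
    diffusion: Callable[[np.ndarray], np.ndarray]
    obs_logdensity: Callable[..., np.ndarray]
    # analytic theta-derivative suppliers for the Girsanov terms; None means
    # "use with_fd_derivatives for a test-grade finite-difference fallback"
    bsq_d1: Optional[Callable] = None
    bsq_d2: Optional[Callable] = None
    psi_d1: Optional[Callable] = None
    psi_d2: Optional[Callable] = None
    # constant diagonal of sigma, if the model has one (fast path)
    diffusion_diag: Optional[np.ndarray] = None
    # (F, c) with a_theta(x) = F x + c, for linear-drift models (Kalman oracle)
    linear_coeffs: Optional[Callable[[np.ndarray], tuple]] = None
    # True when the drift is linear in theta, so the second theta-derivative
    # of psi vanishes identically (skips a large zero tensor in hot loops)
    psi_d2_zero: bool = False
    derivative_grade: str = "analytic"

    def __post_init__(self):
        object.__setattr__(
            self, "initial_state", np.asarray(self.initial_state, dtype=float)
        )
        object.__setattr__(
            self, "positivity_mask", np.asarray(self.positivity_mask, dtype=bool)
        )

    def sigma_matrix(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.diffusion(np.asarray(x, dtype=float)), dtype=float)


def eval_b(model: DiffusionModel, theta, x) -> np.ndarray:
    """Drift under the Girsanov change of measure, b(x) = Sigma(x)^{-1} sigma(x)* a(x).

    Solved as the linear system ``Sigma(x) z = sigma(x)* a(x)``; an explicit
    inverse is never formed.  ``x`` may carry leading batch axes.
    """
    theta = _theta_array(theta)
    x = np.asarray(x, dtype=float)
    a = model.drift(theta, x)
    if model.diffusion_diag is not None:
        return a / model.diffusion_diag
    sig = model.sigma_matrix(x)
    if sig.ndim == 2:  # constant matrix
        Sigma = sig @ sig.T
        rhs = np.einsum("ji,...j->...i", sig, a)
        try:
            return np.linalg.solve(
                np.broadcast_to(Sigma, rhs.shape[:-1] + Sigma.shape), rhs[..., None]
            )[..., 0]
        except np.linalg.LinAlgError as exc:
            raise DegeneracyError(f"singular Sigma at x={x!r}") from exc
    Sigma = np.einsum("...ik,...jk->...ij", sig, sig)
    rhs = np.einsum("...ji,...j->...i", sig, a)
    try:
        return np.linalg.solve(Sigma, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise DegeneracyError(f"singular Sigma at x={x!r}") from exc


def obs_logdensity_derivs(model: DiffusionModel, theta, x, y, order: int = 0):
    """log g_theta(y|x) (order 0) or its first/second theta-derivatives."""
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    theta = _theta_array(theta)
    return model.obs_logdensity(theta, np.asarray(x, float), np.asarray(y, float), order)


# ---------------------------------------------------------------------------
# Gaussian observation model N(x, v * I) with v = theta[var_index]
# ---------------------------------------------------------------------------


def _gaussian_obs_logdensity(var_index: int, d_theta: int, obs_dim: int):
    def obs(theta, x, y, order=0):
        v = theta[var_index]
        if v <= 0.0:
            raise ValueError("observation variance must be positive")
        r = np.sum((np.asarray(y) - np.asarray(x)) ** 2, axis=-1)
        if order == 0:
            return -0.5 * obs_dim * np.log(2.0 * np.pi * v) - r / (2.0 * v)
        if order == 1:
            out = np.zeros(r.shape + (d_theta,))
            out[..., var_index] = -obs_dim / (2.0 * v) + r / (2.0 * v**2)
            return out
        out = np.zeros(r.shape + (d_theta, d_theta))
        out[..., var_index, var_index] = obs_dim / (2.0 * v**2) - r / v**3
        return out

    return obs


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------


def univariate_ou(sigma: float = 1.0, x0: float = 1.0) -> DiffusionModel:
    """dX = -theta1 X dt + sigma dW, observed through N(x, theta2).

    theta = (theta1, theta2) with theta2 > 0 the observation variance.
    """
    s2 = float(sigma) ** 2

    def drift(theta, x):
        return -theta[0] * x

    def bsq_d1(theta, x):
        out = np.zeros(x.shape[:-1] + (2,))
        out[..., 0] = 2.0 * theta[0] * x[..., 0] ** 2 / s2
        return out

    def bsq_d2(theta, x):
        out = np.zeros(x.shape[:-1] + (2, 2))
        out[..., 0, 0] = 2.0 * x[..., 0] ** 2 / s2
        return out

    def psi_d1(theta, x):
        out = np.zeros(x.shape[:-1] + (2, 1))
        out[..., 0, 0] = -x[..., 0] / s2
        return out

    def psi_d2(theta, x):
        return np.zeros(x.shape[:-1] + (2, 2, 1))

    def linear_coeffs(theta):
        return np.array([[-theta[0]]]), np.zeros(1)

    return DiffusionModel(
        name="ou",
        state_dim=1,
        param_dim=2,
        obs_dim=1,
        initial_state=np.array([float(x0)]),
        positivity_mask=np.array([False, True]),
        drift=drift,
        diffusion=lambda x: np.array([[float(sigma)]]),
        diffusion_diag=np.array([float(sigma)]),
        obs_logdensity=_gaussian_obs_logdensity(1, 2, 1),
        bsq_d1=bsq_d1,
        bsq_d2=bsq_d2,
        psi_d1=psi_d1,
        psi_d2=psi_d2,
        psi_d2_zero=True,
        linear_coeffs=linear_coeffs,
    )


def bivariate_ou(sigma=(0.8, 0.6), x0=(1.0, 1.0)) -> DiffusionModel:
    """Two-dimensional OU process with drift (theta1 - theta2 x1, -theta3 x2).

    theta = (theta1, theta2, theta3, theta4); theta4 > 0 is the observation
    variance of the measurement model N2(x, theta4 I).
    """
    s = np.asarray(sigma, dtype=float)
    s2 = s**2

    def drift(theta, x):
        out = np.empty_like(x)
        out[..., 0] = theta[0] - theta[1] * x[..., 0]
        out[..., 1] = -theta[2] * x[..., 1]
        return out

    def bsq_d1(theta, x):
        u1 = theta[0] - theta[1] * x[..., 0]
        out = np.zeros(x.shape[:-1] + (4,))
        out[..., 0] = 2.0 * u1 / s2[0]
        out[..., 1] = -2.0 * x[..., 0] * u1 / s2[0]
        out[..., 2] = 2.0 * theta[2] * x[..., 1] ** 2 / s2[1]
        return out

    def bsq_d2(theta, x):
        x1 = x[..., 0]
        out = np.zeros(x.shape[:-1] + (4, 4))
        out[..., 0, 0] = 2.0 / s2[0]
        out[..., 0, 1] = out[..., 1, 0] = -2.0 * x1 / s2[0]
        out[..., 1, 1] = 2.0 * x1**2 / s2[0]
        out[..., 2, 2] = 2.0 * x[..., 1] ** 2 / s2[1]
        return out

    def psi_d1(theta, x):
        out = np.zeros(x.shape[:-1] + (4, 2))
        out[..., 0, 0] = 1.0 / s2[0]
        out[..., 1, 0] = -x[..., 0] / s2[0]
        out[..., 2, 1] = -x[..., 1] / s2[1]
        return out

    def psi_d2(theta, x):
        return np.zeros(x.shape[:-1] + (4, 4, 2))

    def linear_coeffs(theta):
        F = np.array([[-theta[1], 0.0], [0.0, -theta[2]]])
        c = np.array([theta[0], 0.0])
        return F, c

    return DiffusionModel(
        name="mvou",
        state_dim=2,
        param_dim=4,
        obs_dim=2,
        initial_state=np.asarray(x0, dtype=float),
        positivity_mask=np.array([False, False, False, True]),
        drift=drift,
        diffusion=lambda x: np.diag(s),
        diffusion_diag=s.copy(),
        obs_logdensity=_gaussian_obs_logdensity(3, 4, 2),
        bsq_d1=bsq_d1,
        bsq_d2=bsq_d2,
        psi_d1=psi_d1,
        psi_d2=psi_d2,
        psi_d2_zero=True,
        linear_coeffs=linear_coeffs,
    )


def fitzhugh_nagumo(sigma=(0.2, 0.4), x0=(0.0, 0.0)) -> DiffusionModel:
    """Stochastic FitzHugh-Nagumo neuron model with additive diagonal noise.

    dX1 = theta1 (X1 - X1^3 - X2) dt + sigma1 dW1   (membrane potential)
    dX2 = (theta2 X1 - X2 + theta3) dt + sigma2 dW2 (recovery variable)

    theta = (theta1, theta2, theta3, theta4); theta4 > 0 is the observation
    variance of N2(x, theta4 I).  The initial state is not part of the
    estimation problem and defaults to the resting point (0, 0).
    """
    s = np.asarray(sigma, dtype=float)
    s2 = s**2

    def drift(theta, x):
        out = np.empty_like(x)
        x1 = x[..., 0]
        out[..., 0] = theta[0] * (x1 - x1**3 - x[..., 1])
        out[..., 1] = theta[1] * x1 - x[..., 1] + theta[2]
        return out

    def bsq_d1(theta, x):
        x1 = x[..., 0]
        f1 = x1 - x1**3 - x[..., 1]
        u = theta[1] * x1 - x[..., 1] + theta[2]
        out = np.zeros(x.shape[:-1] + (4,))
        out[..., 0] = 2.0 * theta[0] * f1**2 / s2[0]
        out[..., 1] = 2.0 * x1 * u / s2[1]
        out[..., 2] = 2.0 * u / s2[1]
        return out

    def bsq_d2(theta, x):
        x1 = x[..., 0]
        f1 = x1 - x1**3 - x[..., 1]
        out = np.zeros(x.shape[:-1] + (4, 4))
        out[..., 0, 0] = 2.0 * f1**2 / s2[0]
        out[..., 1, 1] = 2.0 * x1**2 / s2[1]
        out[..., 1, 2] = out[..., 2, 1] = 2.0 * x1 / s2[1]
        out[..., 2, 2] = 2.0 / s2[1]
        return out

    def psi_d1(theta, x):
        x1 = x[..., 0]
        out = np.zeros(x.shape[:-1] + (4, 2))
        out[..., 0, 0] = (x1 - x1**3 - x[..., 1]) / s2[0]
        out[..., 1, 1] = x1 / s2[1]
        out[..., 2, 1] = 1.0 / s2[1]
        return out

    def psi_d2(theta, x):
        return np.zeros(x.shape[:-1] + (4, 4, 2))

    return DiffusionModel(
        name="fhn",
        state_dim=2,
        param_dim=4,
        obs_dim=2,
        initial_state=np.asarray(x0, dtype=float),
        positivity_mask=np.array([True, False, False, True]),
        drift=drift,
        diffusion=lambda x: np.diag(s),
        diffusion_diag=s.copy(),
        obs_logdensity=_gaussian_obs_logdensity(3, 4, 2),
        bsq_d1=bsq_d1,
        bsq_d2=bsq_d2,
        psi_d1=psi_d1,
        psi_d2=psi_d2,
        psi_d2_zero=True,
    )


MODELS = {
    "ou": univariate_ou,
    "mvou": bivariate_ou,
    "fhn": fitzhugh_nagumo,
}


def get_model(name: str, **kwargs) -> DiffusionModel:
    try:
        return MODELS[name](**kwargs)
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODELS)}")


def b_squared(model: DiffusionModel, theta, x) -> np.ndarray:
    """||b_theta(x)||^2, the quadratic-variation integrand of the change of measure."""
    b = eval_b(model, theta, x)
    return np.sum(b * b, axis=-1)


def girsanov_psi(model: DiffusionModel, theta, x) -> np.ndarray:
    """The row vector psi = b* Sigma^{-1} sigma* contracted against path increments."""
    b = eval_b(model, theta, x)
    if model.diffusion_diag is not None:
        return b / model.diffusion_diag
    sig = model.sigma_matrix(np.asarray(x, dtype=float))
    Sigma = (
        sig @ sig.T if sig.ndim == 2 else np.einsum("...ik,...jk->...ij", sig, sig)
    )
    z = np.linalg.solve(
        np.broadcast_to(Sigma, b.shape[:-1] + Sigma.shape[-2:]), b[..., None]
    )[..., 0]
    return np.einsum(
        "...i,...ij->...j", z, np.broadcast_to(sig, b.shape[:-1] + sig.shape[-2:])
    )


# ---------------------------------------------------------------------------
# Finite-difference derivative fallback (test-grade, for user models)
# ---------------------------------------------------------------------------


def with_fd_derivatives(model: DiffusionModel, h: float = 1e-5) -> DiffusionModel:
    """Equip a model with central finite-difference theta-derivative suppliers.

    Intended for user-defined models lacking analytic suppliers; accuracy is
    O(h^2) and the second derivatives are noisier, hence test-grade.
    """

    def bsq0(theta, x):
        return b_squared(model, theta, x)

    def psi0(theta, x):
        return girsanov_psi(model, theta, x)

    d_theta = model.param_dim

    def _grad(fun, theta, x, extra_ndim):
        theta = np.asarray(theta, dtype=float)
        cols = []
        for i in range(d_theta):
            hp = h * (1.0 + abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += hp
            tm[i] -= hp
            cols.append((fun(tp, x) - fun(tm, x)) / (2.0 * hp))
        return np.stack(cols, axis=-1 - extra_ndim)

    def _hess(fun, theta, x, extra_ndim):
        theta = np.asarray(theta, dtype=float)
        rows = []
        for j in range(d_theta):
            hj = h * (1.0 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += hj
            tm[j] -= hj
            gp = _grad(fun, tp, x, extra_ndim)
            gm = _grad(fun, tm, x, extra_ndim)
            rows.append((gp - gm) / (2.0 * hj))
        out = np.stack(rows, axis=-1 - extra_ndim)  # (..., i, j, extra...)
        return 0.5 * (out + out.swapaxes(-2 - extra_ndim, -1 - extra_ndim))

    return replace(
        model,
        bsq_d1=lambda th, x: _grad(bsq0, th, x, 0),
        bsq_d2=lambda th, x: _hess(bsq0, th, x, 0),
        psi_d1=lambda th, x: _grad(psi0, th, x, 1),
        psi_d2=lambda th, x: _hess(psi0, th, x, 1),
        derivative_grade="finite-difference",
    )


# ---------------------------------------------------------------------------
# Synthetic observation generation
# ---------------------------------------------------------------------------


def simulate_observations(
    model: DiffusionModel,
    theta,
    n: int,
    sim_level: int = 10,
    seed=None,
    return_latent: bool = False,
):
    """Simulate ``y_1..y_n`` from a fine-level Euler path with Gaussian noise.

    The latent path is an Euler-Maruyama trajectory at level ``sim_level``
    (step 2^-sim_level) from the model's initial state; each unit-time state
    is observed through g_theta.  Bit-reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    theta = _theta_array(theta)
    rng = np.random.default_rng(seed)
    d = model.state_dim
    dt = 2.0 ** (-sim_level)
    spu = 2**sim_level
    x = model.initial_state.astype(float).copy()
    latent = np.empty((n, d))
    sqdt = np.sqrt(dt)
    diag = model.diffusion_diag
    for p in range(n):
        dw = rng.standard_normal((spu, d)) * sqdt
        for s in range(spu):
            a = model.drift(theta, x)
            if diag is not None:
                x = x + a * dt + diag * dw[s]
            else:
                x = x + a * dt + model.sigma_matrix(x) @ dw[s]
        if not np.all(np.isfinite(x)):
            raise PropagationError(f"non-finite state while simulating unit time {p + 1}")
        latent[p] = x
    # Gaussian measurement model N(x, v I) with v stored in the last theta
    # component; v = 0 degenerates to noiseless observation of the Euler flow.
    v = float(theta[-1])
    if v < 0.0:
        raise ValueError("observation variance must be non-negative")
    ys = latent[:, : model.obs_dim] + np.sqrt(v) * rng.standard_normal(
        (n, model.obs_dim)
    )
    obs = ObservationSeries(ys)
    if return_latent:
        return obs, latent
    return obs
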