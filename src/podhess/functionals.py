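"""Discretized Girsanov score/Hessian path functionals and Hessian assembly.

For a level-l lattice path x = (x_star, x_Delta, ..., x_T) and observations
y_1..y_n the score functional is the theta-gradient of the discrete
log-density

    log rho_theta(x) = sum_p log g_theta(y_p | x_p)
                       - (Delta/2) sum_k ||b_theta(x_k)||^2
                       + sum_k psi_theta(x_k) . (x_{k+1} - x_k),

with psi = b* Sigma^{-1} sigma* and every coefficient evaluated at the LEFT
endpoint of each Euler cell (the Ito convention of the discretized change of
measure).  The Hessian functional is its theta-Hessian.  Smoothed moments of
(score, score outer product, Hessian functional) assemble into the observed
information: note the assembled matrix is the NEGATIVE Hessian of the log
marginal likelihood.

All evaluators accept arbitrary leading batch axes on the path values, which
lets a particle smoother evaluate thousands of trajectories in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .euler import LatticePath
from .models import (
    DegeneracyError,
    DiffusionModel,
    b_squared,
    girsanov_psi,
    _theta_array,
)

__all__ = [
    "PathFunctionalValues",
    "SmoothedMoments",
    "score_functional",
    "hessian_functional",
    "assemble_hessian",
    "evaluate_path_functionals",
    "discrete_girsanov_loglik",
]


@dataclass(frozen=True)
class PathFunctionalValues:
    """G^l, the outer products G^(i) G^(j), and H^l for one path (or a batch)."""

    score: np.ndarray  # (..., d_theta)
    score_outer: np.ndarray  # (..., d_theta, d_theta)
    hess_fun: np.ndarray  # (..., d_theta, d_theta)


@dataclass(frozen=True)
class SmoothedMoments:
    """Smoothed expectations pi^l(G), pi^l(G G*), pi^l(H)."""

    mean_score: np.ndarray
    mean_outer: np.ndarray
    mean_hess_fun: np.ndarray


def _path_values(path: Union[LatticePath, np.ndarray], level=None):
    if isinstance(path, LatticePath):
        return path.values, path.level
    if level is None:
        raise ValueError("raw path arrays require an explicit level")
    return np.asarray(path, dtype=float), level


def _check_span(values, level, n):
    spu = 2**level
    if values.shape[-2] != n * spu + 1:
        raise ValueError(
            f"path with {values.shape[-2]} grid points does not span n={n} "
            f"unit times at level {level}"
        )
    return spu


def _obs_values(obs):
    return obs.values if hasattr(obs, "values") else np.atleast_2d(np.asarray(obs, float))


def evaluate_path_functionals(
    model: DiffusionModel, theta, path, obs, level=None, order: int = 2
) -> PathFunctionalValues:
    """Evaluate score (and, for order 2, outer and Hessian) functionals.

    ``path`` is a :class:`LatticePath` or an array (..., n_grid, d).  With
    ``order=1`` only the score is computed and the matrix slots are None.
    """
    theta = _theta_array(theta)
    y = _obs_values(obs)
    values, level = _path_values(path, level)
    n = y.shape[0]
    spu = _check_span(values, level, n)
    dt = 2.0 ** (-level)
    left = values[..., :-1, :]
    dx = np.diff(values, axis=-2)
    x_units = values[..., spu::spu, :][..., : model.obs_dim]

    if not np.all(np.isfinite(left)):
        bad = np.argwhere(~np.isfinite(left))
        raise DegeneracyError(f"non-finite path value at grid index {bad[0]}")

    d1_obs = model.obs_logdensity(theta, x_units, y, 1)
    score = (
        d1_obs.sum(axis=-2)
        - 0.5 * dt * model.bsq_d1(theta, left).sum(axis=-2)
        + np.einsum("...kid,...kd->...i", model.psi_d1(theta, left), dx)
    )
    if order == 1:
        return PathFunctionalValues(score=score, score_outer=None, hess_fun=None)
    d2_obs = model.obs_logdensity(theta, x_units, y, 2)
    hess = (
        d2_obs.sum(axis=-3)
        - 0.5 * dt * model.bsq_d2(theta, left).sum(axis=-3)
        + np.einsum("...kijd,...kd->...ij", model.psi_d2(theta, left), dx)
    )
    outer = score[..., :, None] * score[..., None, :]
    return PathFunctionalValues(score=score, score_outer=outer, hess_fun=hess)


def score_functional(model: DiffusionModel, theta, path, obs, level=None) -> np.ndarray:
    """The d_theta-vector G_theta^l(x_T^l) (first theta-derivatives)."""
    return evaluate_path_functionals(model, theta, path, obs, level, order=1).score


def hessian_functional(model: DiffusionModel, theta, path, obs, level=None) -> np.ndarray:
    """The d_theta x d_theta matrix H_theta^l(x_T^l) (second theta-derivatives)."""
    return evaluate_path_functionals(model, theta, path, obs, level, order=2).hess_fun


def assemble_hessian(m: SmoothedMoments) -> np.ndarray:
    """Observed information from smoothed moments.

    Returns ``mean_score mean_score* - mean_outer - mean_hess_fun``; this is
    the negative Hessian of the log marginal likelihood (the matrix a Newton
    ascent step inverts).
    """
    ms = np.asarray(m.mean_score, dtype=float)
    mo = np.asarray(m.mean_outer, dtype=float)
    mh = np.asarray(m.mean_hess_fun, dtype=float)
    if mo.shape != mh.shape or mo.shape[-1] != ms.shape[-1]:
        raise ValueError("inconsistent moment shapes")
    return ms[..., :, None] * ms[..., None, :] - mo - mh


def discrete_girsanov_loglik(model, theta, path, obs, level=None) -> np.ndarray:
    """log rho_theta of a lattice path: observation terms + discrete Girsanov terms.

    This is the scalar whose first/second theta-derivatives the score and
    Hessian functionals compute; used as a finite-difference oracle in tests.
    """
    theta = _theta_array(theta)
    y = _obs_values(obs)
    values, level = _path_values(path, level)
    spu = _check_span(values, level, y.shape[0])
    dt = 2.0 ** (-level)
    left = values[..., :-1, :]
    dx = np.diff(values, axis=-2)
    x_units = values[..., spu::spu, :][..., : model.obs_dim]
    obs_term = model.obs_logdensity(theta, x_units, y, 0).sum(axis=-1)
    bsq = b_squared(model, theta, left).sum(axis=-1)
    drift_term = np.einsum("...kd,...kd->...", girsanov_psi(model, theta, left), dx)
    return obs_term - 0.5 * dt * bsq + drift_term
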