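"""Euler-Maruyama transitions and the coupled proposal kernels.

Level ``l`` discretizes time with step ``Delta_l = 2**-l``.  A unit-time
segment at level l therefore has ``2**l`` new grid points; by convention a
segment excludes its left endpoint and includes the right one, so
concatenating segments over k = 1..n reproduces the lattice
``(x_star, x_{Delta_l}, ..., x_T)`` without duplicates.

Couplings:

* same-level pair kernel: two trajectories advanced with the *same* Brownian
  increments (drives the coupled conditional particle filter);
* two-level kernel: fine trajectories advanced with level-l increments and
  coarse trajectories with the sums of consecutive pairs of those increments
  (never re-drawn), which is what makes fine-minus-coarse differences shrink
  at the strong rate of the Euler scheme.

All propagation helpers are vectorized over arbitrary leading batch axes of
the state, which is how the particle filters advance whole particle systems
(and batches of independent chains) in single numpy sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import DiffusionModel, PropagationError, _theta_array

__all__ = [
    "LatticePath",
    "BrownianIncrements",
    "euler_step",
    "coupled_pair_unit",
    "coupled_two_level_unit",
    "marginal_two_level_unit",
    "simulate_prior_path",
    "simulate_prior_path_two_level",
]


@dataclass(frozen=True)
class LatticePath:
    """A level-l trajectory on the grid 0, Delta_l, ..., T (values include t=0)."""

    level: int
    values: np.ndarray  # (n_grid, d)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def step(self) -> float:
        return 2.0 ** (-self.level)

    @property
    def n_units(self) -> int:
        return (self.values.shape[0] - 1) // (2**self.level)

    def __eq__(self, other):
        return (
            isinstance(other, LatticePath)
            and self.level == other.level
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class BrownianIncrements:
    """Increment record; each row is distributed N(0, Delta_l I) under simulation."""

    level: int
    increments: np.ndarray  # (n_steps, ..., d)


def euler_step(model: DiffusionModel, theta, x, dw, dt: float):
    """One Euler-Maruyama step: x + a_theta(x) dt + sigma(x) dw."""
    if dt <= 0.0:
        raise ValueError("step size must be positive")
    theta = _theta_array(theta)
    x = np.asarray(x, dtype=float)
    dw = np.asarray(dw, dtype=float)
    out = _step(model, theta, x, dw, dt)
    if not np.all(np.isfinite(out)):
        raise PropagationError("non-finite state after Euler step")
    return out


def _step(model, theta, x, dw, dt):
    a = model.drift(theta, x)
    if model.diffusion_diag is not None:
        return x + a * dt + model.diffusion_diag * dw
    sig = model.sigma_matrix(x)
    if sig.ndim == 2:
        return x + a * dt + np.einsum("ij,...j->...i", sig, dw)
    return x + a * dt + np.einsum("...ij,...j->...i", sig, dw)


def propagate_segment(model, theta, x, dW, dt, check: bool = True):
    """Advance ``x`` through ``dW.shape[0]`` Euler steps; return the new points.

    ``x``: (..., d); ``dW``: (n_steps, ..., d).  Output: (n_steps, ..., d),
    left endpoint excluded.  Raises :class:`PropagationError` on blow-up.
    """
    steps = dW.shape[0]
    shape = np.broadcast_shapes(np.shape(x), dW.shape[1:])
    out = np.empty((steps,) + shape)
    cur = x
    for s in range(steps):
        cur = _step(model, theta, cur, dW[s], dt)
        out[s] = cur
    if check and not np.all(np.isfinite(out[-1])):
        raise PropagationError("non-finite state during unit-segment propagation")
    return out


def coarsen_increments(dW_fine: np.ndarray) -> np.ndarray:
    """Sum consecutive pairs of fine increments; never re-drawn."""
    if dW_fine.shape[0] % 2 != 0:
        raise ValueError("need an even number of fine increments")
    return dW_fine[0::2] + dW_fine[1::2]


def draw_increments(rng, level: int, n_units: int, shape, d: int) -> np.ndarray:
    """Draw N(0, Delta_l I) increments for n_units unit intervals."""
    dt = 2.0 ** (-level)
    return rng.standard_normal((n_units * 2**level, *shape, d)) * np.sqrt(dt)


# ---------------------------------------------------------------------------
# Spec-level unit kernels (single trajectories; the particle filters use the
# same propagate_segment/coarsen_increments primitives on batched states)
# ---------------------------------------------------------------------------


def coupled_pair_unit(model, theta, x, x_bar, level: int, seed=None):
    """Advance two trajectories one unit of time with shared increments.

    Returns two segments of ``2**level`` points each.  Equal inputs give
    bit-identical outputs (common-noise faithfulness).
    """
    theta = _theta_array(theta)
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    dW = draw_increments(rng, level, 1, (), x.shape[-1])
    dt = 2.0 ** (-level)
    seg = propagate_segment(model, theta, x, dW, dt)
    seg_bar = propagate_segment(model, theta, np.asarray(x_bar, dtype=float), dW, dt)
    return seg, seg_bar


def coupled_two_level_unit(
    model, theta, x_f, x_bar_f, x_c, x_bar_c, fine_level: int, seed=None
):
    """Advance a four-trajectory system one unit of time.

    One level-l increment stream drives all four trajectories: both fine
    trajectories consume it directly and both coarse trajectories consume the
    sums of consecutive pairs.  Returns ((fine, fine_bar), (coarse,
    coarse_bar), increment record); the record exposes the fine increments so
    the summation contract is assertable.
    """
    if fine_level < 1:
        raise ValueError("fine_level must be >= 1")
    theta = _theta_array(theta)
    rng = np.random.default_rng(seed)
    x_f = np.asarray(x_f, dtype=float)
    d = x_f.shape[-1]
    dW = draw_increments(rng, fine_level, 1, (), d)
    dWc = coarsen_increments(dW)
    dtf = 2.0 ** (-fine_level)
    fine = propagate_segment(model, theta, x_f, dW, dtf)
    fine_bar = propagate_segment(model, theta, np.asarray(x_bar_f, float), dW, dtf)
    coarse = propagate_segment(model, theta, np.asarray(x_c, float), dWc, 2 * dtf)
    coarse_bar = propagate_segment(
        model, theta, np.asarray(x_bar_c, float), dWc, 2 * dtf
    )
    return (fine, fine_bar), (coarse, coarse_bar), BrownianIncrements(fine_level, dW)


def marginal_two_level_unit(model, theta, x_f, x_c, fine_level: int, seed=None):
    """Two-trajectory marginal of the four-trajectory kernel (one fine, one coarse)."""
    if fine_level < 1:
        raise ValueError("fine_level must be >= 1")
    theta = _theta_array(theta)
    rng = np.random.default_rng(seed)
    x_f = np.asarray(x_f, dtype=float)
    dW = draw_increments(rng, fine_level, 1, (), x_f.shape[-1])
    dtf = 2.0 ** (-fine_level)
    fine = propagate_segment(model, theta, x_f, dW, dtf)
    coarse = propagate_segment(
        model, theta, np.asarray(x_c, float), coarsen_increments(dW), 2 * dtf
    )
    return fine, coarse


# ---------------------------------------------------------------------------
# Prior path simulation (initial distributions of the coupled chains)
# ---------------------------------------------------------------------------


def simulate_prior_path(model, theta, n: int, level: int, rng, shape=()) -> np.ndarray:
    """Euler prior trajectories from x_star; returns (*shape, n*2**level + 1, d)."""
    theta = _theta_array(theta)
    d = model.state_dim
    dW = draw_increments(rng, level, n, shape, d)
    x0 = np.broadcast_to(model.initial_state, (*shape, d))
    seg = propagate_segment(model, theta, x0, dW, 2.0 ** (-level))
    out = np.concatenate([x0[None], seg], axis=0)  # (steps+1, *shape, d)
    return np.moveaxis(out, 0, -2)


def simulate_prior_path_two_level(model, theta, n: int, fine_level: int, rng, shape=()):
    """Coupled fine/coarse Euler prior trajectories sharing one increment stream."""
    if fine_level < 1:
        raise ValueError("fine_level must be >= 1")
    theta = _theta_array(theta)
    d = model.state_dim
    dW = draw_increments(rng, fine_level, n, shape, d)
    x0 = np.broadcast_to(model.initial_state, (*shape, d))
    dtf = 2.0 ** (-fine_level)
    fine = propagate_segment(model, theta, x0, dW, dtf)
    coarse = propagate_segment(model, theta, x0, coarsen_increments(dW), 2 * dtf)
    fine = np.concatenate([x0[None], fine], axis=0)
    coarse = np.concatenate([x0[None], coarse], axis=0)
    return np.moveaxis(fine, 0, -2), np.moveaxis(coarse, 0, -2)
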