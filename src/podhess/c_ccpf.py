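"""Two-level machinery: the coupled-CCPF (C-CCPF) kernel and its ingredients.

To estimate differences of smoothed expectations between discretization
levels l and l-1, four particle systems are evolved jointly: a CCPF pair at
the fine level and a CCPF pair at the coarse level.  One fine Brownian
stream per particle slot drives all four (the coarse systems consume sums of
consecutive pairs of increments), and resampling draws a four-way coupled
index per slot.  Each pair coalesces in finite time, independently of the
other; fine-minus-coarse trajectory differences inherit the strong Euler
rate, which is the source of the level-variance decay used by the
randomized estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cpf import (
    CoupledPairState,
    DEFAULT_N_PARTICLES,
    _check_pmf,
    _inversion_indices_batch,
    _maximal_indices_batch,
    _obs_array,
    _sweep,
)
from .euler import LatticePath, simulate_prior_path_two_level
from .models import _theta_array

__all__ = [
    "QuadState",
    "four_way_coupled_indices",
    "two_level_cpf_init",
    "cccpf_kernel",
    "init_quad",
]


@dataclass(frozen=True)
class QuadState:
    """State of the C-CCPF chain: a fine pair at level l, a coarse pair at l-1."""

    fine_pair: CoupledPairState
    coarse_pair: CoupledPairState

    def __post_init__(self):
        if self.fine_pair.first.level != self.coarse_pair.first.level + 1:
            raise ValueError("fine level must be coarse level + 1")

    @property
    def fine_level(self) -> int:
        return self.fine_pair.first.level


def four_way_coupled_indices(
    r_fine, r_bar_fine, r_coarse, r_bar_coarse, seed=None, coupling: str = "maximal"
):
    """Draw four indices, one per pmf, with within-pair and cross-pair coupling.

    The (fine, fine-bar) and (coarse, coarse-bar) pairs are each coupled by
    the configured pair coupling; a single shared uniform stream ties the two
    pairs so fine and coarse selections are positively correlated.  Each
    index marginally follows its own pmf.
    """
    ws = [np.asarray(_check_pmf(r), dtype=float)
          for r in (r_fine, r_bar_fine, r_coarse, r_bar_coarse)]
    N = ws[0].size
    w = np.stack(ws)[None]  # (1, 4, N)
    rng = np.random.default_rng(seed)
    if coupling == "inversion":
        u = rng.random((1, 1))
        idx = _inversion_indices_batch(w, u)[0, :, 0]
    elif coupling == "maximal":
        idx = _maximal_indices_batch(w, 1, rng)[0, :, 0]
    else:
        raise ValueError(f"unknown coupling {coupling!r}")
    return tuple(int(i) for i in idx)


def two_level_cpf_init(
    model, theta, obs, fine_ref: LatticePath, coarse_ref: LatticePath,
    N: int = DEFAULT_N_PARTICLES, seed=None, coupling: str = "maximal",
):
    """The two-level CPF move used at initialization of the C-CCPF chain.

    One CPF sweep at levels l and l-1 simultaneously: propagation shares the
    fine increment stream (coarse = sums), resampling uses pairwise-coupled
    fine/coarse indices.  Returns one fine and one coarse trajectory.
    """
    if fine_ref.level != coarse_ref.level + 1:
        raise ValueError("fine reference must sit one level above the coarse one")
    theta = _theta_array(theta)
    y = _obs_array(obs)
    if N == 1:
        return fine_ref, coarse_ref
    rng = np.random.default_rng(seed)
    outs, _, _, _ = _sweep(
        model,
        theta,
        y,
        [fine_ref.values[None], coarse_ref.values[None]],
        [fine_ref.level, coarse_ref.level],
        N,
        rng,
        coupling=coupling,
    )
    return (
        LatticePath(fine_ref.level, outs[0][0]),
        LatticePath(coarse_ref.level, outs[1][0]),
    )


def cccpf_kernel(
    model, theta, obs, z: QuadState, N: int = DEFAULT_N_PARTICLES, seed=None,
    coupling: str = "maximal",
) -> QuadState:
    """One step of the C-CCPF Markov kernel.

    Four interacting particle systems with four frozen references; if either
    input pair is equal, the corresponding output pair is equal (per-level
    coalescence is absorbing, independently at the two levels).
    """
    theta = _theta_array(theta)
    y = _obs_array(obs)
    lf = z.fine_level
    rng = np.random.default_rng(seed)
    refs = [
        z.fine_pair.first.values[None],
        z.fine_pair.second.values[None],
        z.coarse_pair.first.values[None],
        z.coarse_pair.second.values[None],
    ]
    outs, _, _, _ = _sweep(
        model, theta, y, refs, [lf, lf, lf - 1, lf - 1], N, rng, coupling=coupling
    )
    return QuadState(
        CoupledPairState(LatticePath(lf, outs[0][0]), LatticePath(lf, outs[1][0])),
        CoupledPairState(
            LatticePath(lf - 1, outs[2][0]), LatticePath(lf - 1, outs[3][0])
        ),
    )


def init_quad(
    model, theta, obs, fine_level: int, N: int = DEFAULT_N_PARTICLES, seed=None,
    coupling: str = "maximal",
) -> QuadState:
    """Draw from the initial distribution of the C-CCPF chain.

    Two independent two-level Euler prior draws (fine and coarse trajectories
    sharing one increment stream within each draw); the first pair receives
    one two-level CPF move, the second stays frozen at its prior draw.
    """
    if fine_level < 1:
        raise ValueError("fine_level must be >= 1")
    theta = _theta_array(theta)
    y = _obs_array(obs)
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    xf, xc = simulate_prior_path_two_level(model, theta, n, fine_level, rng)
    xbf, xbc = simulate_prior_path_two_level(model, theta, n, fine_level, rng)
    first_f, first_c = two_level_cpf_init(
        model,
        theta,
        obs,
        LatticePath(fine_level, xf),
        LatticePath(fine_level - 1, xc),
        N=N,
        seed=rng.integers(2**31),
        coupling=coupling,
    )
    return QuadState(
        CoupledPairState(first_f, LatticePath(fine_level, xbf)),
        CoupledPairState(first_c, LatticePath(fine_level - 1, xbc)),
    )
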