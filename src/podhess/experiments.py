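"""Reproductions of the estimator studies at configurable scale.

Four experiments:

* ``bias_sweep`` -- bias of the truncated randomized Hessian estimator
  against a reference observed information, across truncation levels L, with
  the fitted log-log slope in the step size Delta_L;
* ``increment_variance_sweep`` -- sample variance of the level-l Hessian
  functional increments, summed over matrix entries, against Delta_l;
* ``sgd_optimize`` -- stochastic gradient ascent on the unbiased score;
* ``newton_optimize`` -- (modified) Newton ascent using the unbiased score
  and observed-information estimates.

Cost is accounted in Euler-step operation counts (steps x particles x
systems x sweeps), not wall-clock, so comparisons are hardware-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .models import DiffusionModel, _theta_array
from .oracles import discretized_linear_system, fd_score_hessian, kalman_loglik
from .unbiased import (
    EstimatorSettings,
    LevelDistribution,
    level_distribution,
    unbiased_hessian,
    unbiased_score,
    xi_functional_increments,
)

__all__ = [
    "SweepResult",
    "OptimizerTrace",
    "fit_loglog_slope",
    "kalman_reference_hessian",
    "bias_sweep",
    "increment_variance_sweep",
    "sgd_optimize",
    "newton_optimize",
    "DEFAULT_CONVERGENCE_TOL",
    "THETA_FLOOR",
]

# convergence rule: relative Euclidean distance between the trained and the
# data-generating parameter
DEFAULT_CONVERGENCE_TOL = 0.02
# positivity projection floor for masked parameter components
THETA_FLOOR = 1e-3


def fit_loglog_slope(step_sizes, values):
    """Least-squares slope of log(values) against log(step size), with SE."""
    x = np.log(np.asarray(step_sizes, dtype=float))
    y = np.log(np.asarray(values, dtype=float))
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = coef
    if x.size > 2:
        resid = y - A @ coef
        s2 = resid @ resid / (x.size - 2)
        se = float(np.sqrt(s2 / np.sum((x - x.mean()) ** 2)))
    else:
        se = np.nan
    return float(slope), se, float(intercept)


@dataclass(frozen=True)
class SweepResult:
    """Per-level summaries of a bias or variance sweep, plus the fitted slope."""

    levels: np.ndarray
    step_sizes: np.ndarray
    summary: np.ndarray  # summed-over-entries bias or variance per level
    per_entry: np.ndarray  # (n_levels, d_theta, d_theta)
    slope: float
    slope_se: float
    replicates: int
    meeting_time_max: int = 0


@dataclass(frozen=True)
class OptimizerTrace:
    """Iterates of a stochastic parameter-learning run."""

    thetas: np.ndarray  # (n_iter + 1, d_theta), including the initial point
    converged_at: Optional[int]  # first iterate meeting the distance rule
    rule: str
    learning_rate: Optional[float]
    settings: EstimatorSettings
    target: np.ndarray

    @property
    def n_iterations(self) -> int:
        return self.thetas.shape[0] - 1


def kalman_reference_hessian(model: DiffusionModel, theta, obs, level: Optional[int] = None):
    """Observed information of a linear-drift model by Kalman finite differences.

    ``level=None`` uses the exact unit-time transition (the continuous-time
    reference the discretization bias is measured against); an integer runs
    the recursion on that Euler grid.
    """
    from .oracles import exact_ou_unit_system

    theta = _theta_array(theta)
    if level is None:
        def ll(t):
            return kalman_loglik(exact_ou_unit_system(model, t), obs)
    else:
        def ll(t):
            return kalman_loglik(discretized_linear_system(model, t, level), obs)
    _, neg_hess = fd_score_hessian(ll, theta)
    return neg_hess


def bias_sweep(
    model, theta_true, obs, levels: Sequence[int], M: int,
    reference: np.ndarray = None,
    settings: EstimatorSettings = EstimatorSettings(), seed=None,
    min_reps: int = 64,
) -> SweepResult:
    """Bias of the level-L truncated Hessian estimator per truncation level.

    The truncated estimator's expectation telescopes to the fixed-level
    observed information H^L, so the sweep estimates H^L directly in its
    level-stratified form: per level l it averages R_l independent
    increments Xi^l (R_l = max(min_reps, M 2^-l), mirroring the truncated
    level pmf's average allocation but with a floor that keeps the rare
    coarse-level draws from dominating), assembles partial sums up to each
    L with the product of two independent stack means (exactly unbiased for
    the mean-score product), and reuses the same increments across all
    truncation levels so the fitted slope is not polluted by independent
    noise per level.  Bias is entrywise against ``reference`` (defaulting,
    for linear-drift models, to the exact-transition Kalman observed
    information); the slope of the summed absolute bias against Delta_L
    estimates the weak discretization rate.
    """
    theta_true = _theta_array(theta_true)
    if reference is None:
        reference = kalman_reference_hessian(model, theta_true, obs)
    reference = np.asarray(reference, dtype=float)
    levels = np.asarray(levels, dtype=int)
    L_max = int(levels.max())
    d_th = model.param_dim
    tau_max = 0
    mean_score = np.zeros((L_max + 1, d_th))
    mean_score_tilde = np.zeros((L_max + 1, d_th))
    mean_outer = np.zeros((L_max + 1, d_th, d_th))
    mean_hess = np.zeros((L_max + 1, d_th, d_th))
    for l in range(L_max + 1):
        R_l = max(min_reps, int(np.ceil(M * 0.5**l)))
        base = (int(seed) % 2**31) if seed is not None else None
        inc, diag = xi_functional_increments(
            model, theta_true, obs, l, R_l, settings=settings,
            seed=(base + 101 * l) if base is not None else None,
        )
        inc2, diag2 = xi_functional_increments(
            model, theta_true, obs, l, R_l, settings=settings,
            seed=(base + 101 * l + 50) if base is not None else None, order=1,
        )
        mean_score[l] = inc["score"].mean(axis=0)
        mean_score_tilde[l] = inc2["score"].mean(axis=0)
        mean_outer[l] = inc["outer"].mean(axis=0)
        mean_hess[l] = inc["hess"].mean(axis=0)
        for dg in (diag, diag2):
            tau_max = max(
                tau_max, max(int(t.max(initial=0)) for t in dg["meeting_times"])
            )
    s_cum = np.cumsum(mean_score, axis=0)
    st_cum = np.cumsum(mean_score_tilde, axis=0)
    o_cum = np.cumsum(mean_outer, axis=0)
    h_cum = np.cumsum(mean_hess, axis=0)
    per_entry = np.empty((levels.size, d_th, d_th))
    for i, L in enumerate(levels):
        est = (
            s_cum[L][:, None] * st_cum[L][None, :] - o_cum[L] - h_cum[L]
        )
        per_entry[i] = 0.5 * (est + est.T) - reference
    summed = np.abs(per_entry).sum(axis=(1, 2))
    steps = 0.5 ** levels.astype(float)
    slope, se, _ = fit_loglog_slope(steps, summed)
    return SweepResult(
        levels=levels, step_sizes=steps, summary=summed, per_entry=per_entry,
        slope=slope, slope_se=se, replicates=M, meeting_time_max=tau_max,
    )


def increment_variance_sweep(
    model, theta_true, obs, levels: Sequence[int], reps: int,
    settings: EstimatorSettings = EstimatorSettings(), seed=None,
) -> SweepResult:
    """Sample variance of the level-l Hessian functional increment vs Delta_l.

    Per level l the sweep draws ``reps`` independent increments
    Xi^l(H^(ij)) from coupled two-level chains, computes the entrywise
    sample variance, sums over the d_theta x d_theta entries and fits the
    log-log slope against the step size.  The fitted slope estimates the
    strong coupling rate that justifies the level randomization.
    """
    theta_true = _theta_array(theta_true)
    levels = np.asarray(levels, dtype=int)
    if np.any(levels < 1):
        raise ValueError("variance sweep needs levels >= 1")
    per_entry = np.empty((levels.size, model.param_dim, model.param_dim))
    tau_max = 0
    for i, l in enumerate(levels):
        inc, diag = xi_functional_increments(
            model, theta_true, obs, int(l), reps, settings=settings,
            seed=(int(seed) % 2**31 + 13 * int(l)) if seed is not None else None,
        )
        per_entry[i] = inc["hess"].var(axis=0, ddof=1)
        tau_max = max(tau_max, max(int(t.max()) for t in diag["meeting_times"]))
    summed = per_entry.sum(axis=(1, 2))
    steps = 0.5 ** levels.astype(float)
    slope, se, _ = fit_loglog_slope(steps, summed)
    return SweepResult(
        levels=levels, step_sizes=steps, summary=summed, per_entry=per_entry,
        slope=slope, slope_se=se, replicates=reps, meeting_time_max=tau_max,
    )


# ---------------------------------------------------------------------------
# Parameter learning
# ---------------------------------------------------------------------------


def _project(model, theta):
    out = np.asarray(theta, dtype=float).copy()
    mask = model.positivity_mask
    out[mask] = np.maximum(out[mask], THETA_FLOOR)
    return out


def _converged(theta, target, tol):
    return np.linalg.norm(theta - target) / np.linalg.norm(target) <= tol


def sgd_optimize(
    model, obs, theta_init, rate: float, theta_true,
    dist: LevelDistribution = None, M: int = 1,
    settings: EstimatorSettings = EstimatorSettings(),
    max_iter: int = 500, tol: float = DEFAULT_CONVERGENCE_TOL,
    seed=None, score_fn: Callable = None,
) -> OptimizerTrace:
    """Stochastic gradient ascent with the unbiased score estimator.

    Update: theta <- theta + rate * G_hat(theta), with masked components
    projected onto a small positive floor.  Stops when the relative
    Euclidean distance to ``theta_true`` drops below ``tol`` or after
    ``max_iter`` iterations.  ``score_fn(theta, k)`` overrides the estimator
    (used with exact oracles in tests).
    """
    if rate <= 0:
        raise ValueError("learning rate must be positive")
    theta = _project(model, _theta_array(theta_init))
    target = _theta_array(theta_true)
    thetas = [theta.copy()]
    converged_at = None
    for k in range(max_iter):
        if _converged(theta, target, tol):
            converged_at = k
            break
        if score_fn is not None:
            g = np.asarray(score_fn(theta, k), dtype=float)
        else:
            g, _ = unbiased_score(
                model, theta, obs, dist, settings=settings, M=M,
                seed=(int(seed) % 2**31 + k) if seed is not None else None,
            )
        theta = _project(model, theta + rate * g)
        if not np.all(np.isfinite(theta)) or np.linalg.norm(theta) > 1e6:
            raise RuntimeError(f"SGD diverged at iteration {k}")
        thetas.append(theta.copy())
    else:
        if _converged(theta, target, tol):
            converged_at = max_iter
    return OptimizerTrace(
        thetas=np.asarray(thetas), converged_at=converged_at, rule="SGD",
        learning_rate=rate, settings=settings, target=target,
    )


def newton_optimize(
    model, obs, theta_init, theta_true,
    dist: LevelDistribution = None, M: int = 1,
    settings: EstimatorSettings = EstimatorSettings(),
    variant: str = "modified", max_iter: int = 50,
    tol: float = DEFAULT_CONVERGENCE_TOL,
    ridge: float = 1e-4, score_norm_gate: float = 0.1, gated_rate: float = 0.002,
    seed=None, score_fn: Callable = None, hessian_fn: Callable = None,
) -> OptimizerTrace:
    """(Modified) Newton ascent with unbiased score and observed information.

    The estimator returns the negative Hessian H_hat of the log-likelihood,
    so the ascent update is ``theta <- theta + H_hat^{-1} G_hat``.  The
    ``modified`` variant zeroes the off-diagonal entries of H_hat, adds
    ``ridge`` to the diagonal to avoid singularity, and once the score norm
    falls below ``score_norm_gate`` scales the step by ``gated_rate`` (the
    damping used near the optimum, where the stochastic score is noise
    dominated).
    """
    if variant not in ("full", "modified"):
        raise ValueError("variant must be 'full' or 'modified'")
    theta = _project(model, _theta_array(theta_init))
    target = _theta_array(theta_true)
    thetas = [theta.copy()]
    converged_at = None
    for k in range(max_iter):
        if _converged(theta, target, tol):
            converged_at = k
            break
        kseed = (int(seed) % 2**31 + 1000 * k) if seed is not None else None
        if score_fn is not None:
            g = np.asarray(score_fn(theta, k), dtype=float)
        else:
            g, _ = unbiased_score(
                model, theta, obs, dist, settings=settings, M=M, seed=kseed,
            )
        if hessian_fn is not None:
            H = np.asarray(hessian_fn(theta, k), dtype=float)
        else:
            est = unbiased_hessian(
                model, theta, obs, dist, M=M, settings=settings,
                seed=kseed + 1 if kseed is not None else None,
            )
            H = est.aggregate_product_of_means
        if variant == "modified":
            H = np.diag(np.diag(H)) + ridge * np.eye(H.shape[0])
            step = g / np.diag(H)
            if np.linalg.norm(g) < score_norm_gate:
                step = gated_rate * step
        else:
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "singular Hessian estimate; use variant='modified'"
                ) from exc
        theta = _project(model, theta + step)
        if not np.all(np.isfinite(theta)) or np.linalg.norm(theta) > 1e6:
            raise RuntimeError(f"Newton iteration {k} diverged")
        thetas.append(theta.copy())
    else:
        if _converged(theta, target, tol):
            converged_at = max_iter
    return OptimizerTrace(
        thetas=np.asarray(thetas), converged_at=converged_at,
        rule="Newton" if variant == "full" else "modified-Newton",
        learning_rate=gated_rate, settings=settings, target=target,
    )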