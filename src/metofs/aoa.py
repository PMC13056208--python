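"""Arithmetic Optimization Algorithm (AOA) operators.

AOA explores with the high-dispersion Division / Multiplication operators
and exploits with the low-dispersion Subtraction / Addition operators,
scheduled by the Math Optimizer Accelerated value (MOA, linear in t) and
the Math Optimizer Probability (MOP, decaying in t).  The module serves
both as a standalone optimizer and as the donor of the operators injected
into the METO hybrid.

Fidelity notes: the exploration rule is implemented exactly as printed,
i.e. with the scale term ``((UB - LB) + LB)`` and *without* the search
control parameter mu (canonical AOA multiplies (UB - LB) by mu there);
``AoaParams.mu_in_exploration`` restores the canonical form.  The
division branch is grouped as ``Xb / (MOP + eps) * scale`` — the only
grouping in which eps prevents division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optim_core import (
    Objective,
    OptimizerResult,
    Population,
    RngStream,
    SearchSpace,
    clip_to_bounds,
    evaluate_and_update_best,
    init_population,
    register_optimizer,
)

__all__ = [
    "AoaParams",
    "compute_moa",
    "compute_mop",
    "aoa_explore",
    "aoa_exploit",
    "aoa_step",
    "aoa_run",
]


@dataclass
class AoaParams:
    """AOA control parameters.

    ``min``/``max`` bound the MOA schedule (source gives no values; 0.2
    and 0.9 are common settings), ``alpha`` is the MOP sensitivity (5),
    ``mu`` the search control (0.5), ``epsilon`` the division guard
    (described as a "small integer"; a literal integer would defeat its
    purpose, so a small float is used).
    """

    min: float = 0.2
    max: float = 0.9
    alpha: float = 5.0
    mu: float = 0.5
    epsilon: float = 1e-12
    mu_in_exploration: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.min < self.max <= 1.0):
            raise ValueError("require 0 <= min < max <= 1 for the MOA bounds")
        if self.alpha <= 0 or not (0.0 < self.mu <= 1.0) or self.epsilon <= 0:
            raise ValueError("invalid AOA parameters")


def compute_moa(t: int, tmax: int, params: AoaParams) -> float:
    """MOA(t) = Min + t (Max - Min) / tmax (linear phase switch)."""
    return params.min + t * (params.max - params.min) / tmax


def compute_mop(t: int, tmax: int, params: AoaParams) -> float:
    """MOP(t) = 1 - t^(1/alpha) / tmax^(1/alpha) (decays 1 -> 0)."""
    return 1.0 - (t ** (1.0 / params.alpha)) / (tmax ** (1.0 / params.alpha))


def _explore_scale(lb: np.ndarray, ub: np.ndarray, params: AoaParams) -> np.ndarray:
    if params.mu_in_exploration:
        return (ub - lb) * params.mu + lb
    return (ub - lb) + lb  # as printed (mu-free)


def aoa_explore(
    xb: np.ndarray,
    mop: float,
    lb: np.ndarray,
    ub: np.ndarray,
    params: AoaParams,
    rng: RngStream,
) -> np.ndarray:
    """Division / Multiplication update of one row (r2 drawn per dimension).

    r2 < 0.5:  Xb_j / (MOP + eps) * scale_j      (Division)
    else:      Xb_j * MOP * scale_j              (Multiplication)
    """
    r2 = rng.uniform(xb.size)
    scale = _explore_scale(lb, ub, params)
    div = xb / (mop + params.epsilon) * scale
    mul = xb * mop * scale
    return np.where(r2 < 0.5, div, mul)


def aoa_exploit(
    xb: np.ndarray,
    mop: float,
    lb: np.ndarray,
    ub: np.ndarray,
    params: AoaParams,
    rng: RngStream,
) -> np.ndarray:
    """Subtraction / Addition update of one row (r3 drawn per dimension).

    r3 < 0.5:  Xb_j - MOP * ((UB_j - LB_j) mu + LB_j)   (Subtraction)
    else:      Xb_j + MOP * ((UB_j - LB_j) mu + LB_j)   (Addition)
    """
    r3 = rng.uniform(xb.size)
    step = mop * ((ub - lb) * params.mu + lb)
    return np.where(r3 < 0.5, xb - step, xb + step)


def aoa_step(
    pop: Population,
    t: int,
    tmax: int,
    space: SearchSpace,
    params: AoaParams,
    f: Objective,
    rng: RngStream,
) -> Population:
    """One AOA iteration: r1 per solution selects explore (r1 > MOA) or
    exploit; operator choice per dimension; clip, evaluate, elitist update."""
    moa = compute_moa(t, tmax, params)
    mop = compute_mop(t, tmax, params)
    new_x = np.empty_like(pop.x)
    for i in range(pop.n):
        r1 = rng.uniform()
        if r1 > moa:
            new_x[i] = aoa_explore(pop.xb, mop, space.lb, space.ub, params, rng)
        else:
            new_x[i] = aoa_exploit(pop.xb, mop, space.lb, space.ub, params, rng)
    pop.x = clip_to_bounds(new_x, space)
    evaluate_and_update_best(pop, f)
    return pop


def aoa_run(
    space: SearchSpace,
    objective: Objective,
    n: int = 20,
    tmax: int = 100,
    rng: RngStream | int | None = None,
    params: AoaParams | None = None,
) -> OptimizerResult:
    """Run standalone AOA under the shared optimizer contract."""
    if not hasattr(rng, "uniform"):
        rng = RngStream(rng)
    params = params or AoaParams()
    pop = init_population(space, n, rng)
    evaluate_and_update_best(pop, objective)
    trace = np.empty(tmax)
    for t in range(1, tmax + 1):
        pop = aoa_step(pop, t, tmax, space, params, objective, rng)
        trace[t - 1] = pop.fitb
    return OptimizerResult(xb=pop.xb, fitb=pop.fitb, trace=trace)


register_optimizer("aoa", aoa_run)
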